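"""96-channel trinucleotide mutation spectra and signature-exposure refitting.

A mutation spectrum counts single-base substitutions in their +/-1 bp genomic
context over the 96 pyrimidine-centric channels ``X[R>A]Y`` (R in {C, T};
X, Y in {A, C, G, T}), in the conventional lexicographic catalogue order
(C>A block first). Purine-centred mutations are mapped to the
reverse-complement pyrimidine channel, e.g. ``G[G>A]A -> T[C>T]C``.

Refitting decomposes a normalised spectrum onto a catalogue of signature
columns by constrained least squares::

    minimise  || f - M w ||_2^2   subject to  w >= 0,  sum(w) = 1

which is the "frequency-model" objective of standard refitting tools. The
convex program is solved deterministically with SLSQP from a fixed uniform
start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import MutationRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_channels() -> list[str]:
    channels = []
    for ref in "CT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    channels.append(f"{five}[{ref}>{alt}]{three}")
    return channels


#: COSMIC-style channel order: substitution blocks C>A, C>G, C>T, T>A, T>C,
#: T>G; flanks lexicographic within each block.
CHANNELS_96: tuple[str, ...] = tuple(_build_channels())
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its 3-mer context to its pyrimidine channel."""
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in "AG":  # purine-centred: reverse-complement the triplet
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationSpectrum:
    """Counts (or frequencies) over the 96 trinucleotide channels."""

    values: np.ndarray
    n_mutations: int
    n_dropped_edge: int = 0
    n_ref_mismatch: int = 0

    def normalized(self) -> np.ndarray:
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalise an all-zero spectrum")
        return self.values / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(CHANNELS_96))


def build_spectrum(mutations: Iterable[MutationRecord],
                   genome: Mapping[str, str]) -> MutationSpectrum:
    """Tally mutations into the 96 channels using the genome for context.

    Mutations whose ref base disagrees with the genome are counted and
    skipped (record-level error); so are mutations at contig edges, which
    lack one flanking base.
    """
    values = np.zeros(96)
    n = dropped = mismatch = 0
    for m in mutations:
        seq = genome.get(m.chrom)
        if seq is None or m.pos < 1 or m.pos + 2 > len(seq):
            dropped += 1
            continue
        context = seq[m.pos - 1:m.pos + 2].upper()
        if context[1] != m.ref:
            mismatch += 1
            continue
        if any(b not in "ACGT" for b in context):
            dropped += 1
            continue
        values[_CHANNEL_INDEX[channel_of(m.ref, m.alt, context)]] += 1
        n += 1
    return MutationSpectrum(values=values, n_mutations=n,
                            n_dropped_edge=dropped, n_ref_mismatch=mismatch)


@dataclass
class SignatureCatalog:
    """Named 96 x K column-stochastic signature matrix."""

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match 96 x "
                f"{len(self.names)} signatures")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")

    @property
    def k(self) -> int:
        return len(self.names)


def read_catalog(path) -> SignatureCatalog:
    """Read a signature catalogue TSV (first column channel label)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CHANNELS_96 if c not in frame.index]
    if missing:
        raise ValueError(f"catalogue missing {len(missing)} channels, "
                         f"e.g. {missing[:3]}")
    frame = frame.loc[list(CHANNELS_96)]
    return SignatureCatalog(names=list(frame.columns),
                            matrix=frame.to_numpy(dtype=float))


def write_catalog(catalog: SignatureCatalog, path) -> None:
    pd.DataFrame(catalog.matrix, index=list(CHANNELS_96),
                 columns=catalog.names).to_csv(path, sep="\t",
                                               index_label="channel")


@dataclass
class ExposureVector:
    """Refitted signature weights on the probability simplex."""

    names: list[str]
    weights: np.ndarray
    residual_norm: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.names)


def refit_exposures(spectrum: MutationSpectrum,
                    catalog: SignatureCatalog) -> ExposureVector:
    """Refit signature exposures by simplex-constrained least squares.

    The result is scale-invariant in the spectrum counts (the spectrum is
    normalised first). Raises for an all-zero spectrum.
    """
    f = spectrum.normalized()
    M = catalog.matrix
    k = catalog.k

    def objective(w):
        r = M @ w - f
        return r @ r

    def gradient(w):
        return 2 * M.T @ (M @ w - f)

    x0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        objective, x0, jac=gradient, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    residual = float(np.linalg.norm(M @ w - f))
    return ExposureVector(names=list(catalog.names), weights=w,
                          residual_norm=residual)


def compare_exposures(exposures_subset: ExposureVector,
                      exposures_whole: ExposureVector) -> pd.DataFrame:
    """Per-signature exposure difference (subset - whole), ranked by |diff|."""
    if exposures_subset.names != exposures_whole.names:
        raise ValueError("exposure vectors use different catalogues")
    diff = exposures_subset.weights - exposures_whole.weights
    frame = pd.DataFrame({
        "signature": exposures_subset.names,
        "exposure_subset": exposures_subset.weights,
        "exposure_whole": exposures_whole.weights,
        "difference": diff,
    })
    order = np.argsort(-np.abs(diff), kind="stable")
    return frame.iloc[order].reset_index(drop=True)
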