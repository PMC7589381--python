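"""Indel-frequency estimation from mixed Sanger-like traces.

A chimeric or heterozygous plant yields a sequencing trace that is a
superposition of alleles: downstream of the Cas9 cut, each allele's
basecalls are shifted by its net indel size, so the four-channel signal
in a window after the cut is (approximately) a nonnegative mixture of
the control trace shifted by every candidate indel size.  Solving a
nonnegative least-squares problem over those shifted basis traces
recovers the per-indel-size frequencies and an R² goodness of fit —
the same idea as the TIDE method for quantifying editing from Sanger
chromatograms.

Traces are stored at sub-base resolution (a Gaussian peak per base, a
fixed number of positions per base); the decomposition samples each
channel at the peak centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["TraceSet", "Decomposition", "decompose_trace"]

CHANNELS = "ACGT"


@dataclass
class TraceSet:
    """Four-channel chromatogram-like signal.

    ``channels`` is a (length, 4) nonnegative array in A, C, G, T order;
    ``spacing`` is the number of positions per base; ``sequence`` holds
    the base-called sequence (argmax channel at each peak centre).
    """

    channels: np.ndarray
    spacing: int
    sequence: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise ValueError("channels must be a (length, 4) array")
        if (self.channels < 0).any():
            raise ValueError("intensities must be nonnegative")
        if not self.sequence:
            self.sequence = self.base_call()

    @property
    def n_bases(self) -> int:
        return self.channels.shape[0] // self.spacing

    def peak_matrix(self) -> np.ndarray:
        """(n_bases, 4) channel intensities sampled at peak centres."""
        centres = np.arange(self.n_bases) * self.spacing + self.spacing // 2
        return self.channels[centres]

    def base_call(self) -> str:
        peaks = self.peak_matrix()
        return "".join(CHANNELS[i] for i in peaks.argmax(axis=1))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.channels, columns=list(CHANNELS))
        df.insert(0, "position", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, spacing: int = 10) -> "TraceSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df[list(CHANNELS)].to_numpy(float), spacing=spacing)


@dataclass
class Decomposition:
    """Result of a trace decomposition fit.

    ``frequencies`` maps indel size (negative = deletion, 0 = unedited)
    to its mixture fraction, normalised to sum to 1; ``raw_weights``
    are the unnormalised NNLS solutions.  Fits with R² below 0.9 are
    flagged low-confidence.
    """

    frequencies: dict[int, float]
    raw_weights: dict[int, float]
    r_squared: float
    window: tuple[int, int]
    low_confidence: bool = field(init=False)

    def __post_init__(self) -> None:
        self.low_confidence = self.r_squared < 0.9

    def summary(self) -> str:
        lines = [
            f"Trace decomposition over window {self.window} "
            f"(bases downstream of cut)",
            f"R^2 = {self.r_squared:.4f}"
            + ("  [low confidence]" if self.low_confidence else ""),
            "indel_size  frequency",
        ]
        for size in sorted(self.frequencies):
            f = self.frequencies[size]
            if f > 1e-4:
                lines.append(f"{size:+10d}  {f:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indel_size": sorted(self.frequencies),
                "frequency": [self.frequencies[s] for s in sorted(self.frequencies)],
            }
        )


def decompose_trace(
    sample: TraceSet,
    control: TraceSet,
    cut_index: int,
    max_indel: int = 10,
    window: tuple[int, int] = (10, 60),
) -> Decomposition:
    """Estimate indel-size frequencies in ``sample`` against ``control``.

    ``cut_index`` is the cut position in base coordinates of the control.
    ``window`` is the analysed base range downstream of the cut
    (default 10–60).  Basis traces are built by shifting the control by
    every size in ±1..±``max_indel``: a deletion of k aligns sample base
    b with control base b+k, an insertion of k with control base b−k
    (window bases that would fall inside the unknown inserted sequence
    are dropped from the fit).  Nonnegative least squares over the
    flattened four-channel window yields the mixture weights.
    """
    w0, w1 = window
    if w1 <= w0 or w0 < 0:
        raise ValueError("window must be a nonempty range downstream of the cut")
    ctrl = control.peak_matrix()
    samp = sample.peak_matrix()
    if float(ctrl.std()) == 0.0:
        raise ValueError("degenerate control trace (zero variance)")

    sizes = list(range(-max_indel, max_indel + 1))
    lo = cut_index + w0
    hi = min(cut_index + w1, samp.shape[0], ctrl.shape[0] - max_indel)
    if hi <= lo:
        raise ValueError("analysis window exceeds the trace")
    bases = np.arange(lo, hi)

    # drop window bases that fall inside the inserted (unknown) region of
    # any insertion basis: base b of an insertion of size k reads control
    # base b-k, invalid when b-k < cut_index
    valid = np.ones(len(bases), dtype=bool)
    for k in sizes:
        if k > 0:
            valid &= bases - k >= cut_index
    bases = bases[valid]
    if len(bases) < len(sizes):
        raise ValueError("analysis window too small for the requested max_indel")

    basis = np.empty((len(bases) * 4, len(sizes)))
    for j, k in enumerate(sizes):
        # indel size k (negative = deletion): sample base b <- control base b - k
        basis[:, j] = ctrl[bases - k].ravel()
    y = samp[bases].ravel()

    weights, _ = nnls(basis, y)
    fitted = basis @ weights
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = max(0.0, min(1.0, r2))

    total = float(weights.sum())
    if total <= 0:
        raise ValueError("degenerate fit: all mixture weights zero")
    freqs = {k: float(w / total) for k, w in zip(sizes, weights)}
    raw = {k: float(w) for k, w in zip(sizes, weights)}
    return Decomposition(frequencies=freqs, raw_weights=raw, r_squared=r2,
                         window=(w0, w1))
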