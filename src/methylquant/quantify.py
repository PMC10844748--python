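"""XIC extraction, AUC integration and methylation-state stoichiometry.

A targeted acquisition yields (rt, m/z, intensity) observations.  For each
methylation state of the monitored peptide we extract an ion chromatogram
within a ppm tolerance window around the theoretical m/z (default +-10 ppm),
integrate its area under the curve by the trapezoidal rule, normalise the
per-state areas into fractions p0..p3, and summarise them as the weighted
methylation fraction

    100 * (0*p0 + 1*p1 + 2*p2 + 3*p3) / reference_max

where reference_max is 2 when full dimethylation is the theoretical
maximum (the yeast in-vivo end state) and 3 for full trimethylation
(in-vitro end state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .masscalc import STATE_LABELS, PrmTarget

__all__ = [
    "ChromatogramTrace",
    "XICWindow",
    "SpeciesQuant",
    "MethylationProfile",
    "extract_xic",
    "integrate_auc",
    "state_fractions",
    "methylation_fraction",
    "quantify_states",
]


@dataclass
class ChromatogramTrace:
    """Time-ordered (rt, m/z, intensity) observations from one acquisition."""

    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    acquisition_id: str = ""

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.rt.shape == self.mz.shape == self.intensity.shape):
            raise ValueError("rt, mz and intensity must have equal length")
        if self.rt.size and np.any(np.diff(self.rt) < 0):
            order = np.argsort(self.rt, kind="stable")
            self.rt, self.mz, self.intensity = (
                self.rt[order],
                self.mz[order],
                self.intensity[order],
            )
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.rt.size

    @classmethod
    def from_tsv(cls, path, acquisition_id: str | None = None) -> "ChromatogramTrace":
        """Read a long-format trace TSV with columns rt_s, mz, intensity."""
        df = pd.read_csv(path, sep="\t")
        missing = {"rt_s", "mz", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"trace file missing columns: {sorted(missing)}")
        return cls(
            df["rt_s"].to_numpy(float),
            df["mz"].to_numpy(float),
            df["intensity"].to_numpy(float),
            acquisition_id or str(path),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"rt_s": self.rt, "mz": self.mz, "intensity": self.intensity}
        ).to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class XICWindow:
    """A ppm tolerance window around a target m/z, with an optional rt range."""

    target_mz: float
    tol_ppm: float = 10.0
    rt_range: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        if self.rt_range is not None and self.rt_range[0] >= self.rt_range[1]:
            raise ValueError("rt_range start must precede end")

    def half_width(self) -> float:
        return self.target_mz * self.tol_ppm * 1e-6

    def overlaps(self, other: "XICWindow") -> bool:
        return abs(self.target_mz - other.target_mz) <= (
            self.half_width() + other.half_width()
        )


@dataclass(frozen=True)
class SpeciesQuant:
    """Integrated abundance of one peptide species (one methylation state)."""

    state_label: str
    auc: float
    source: str = "precursor"  # or "fragment_sum"
    phospho: bool = False

    def __post_init__(self):
        if self.auc < 0:
            raise ValueError("auc must be non-negative")


@dataclass
class MethylationProfile:
    """Per-state fractions p0..p3 and the weighted methylation fraction.

    ``defined`` is False when total signal was zero; fractions are then NaN
    and the methylation fraction undefined.  ``over_reference`` flags a
    profile whose weighted sum exceeds the reference maximum (p3 > 0 with
    reference_max 2); the value is reported as-is, never clamped.
    """

    fractions: np.ndarray
    reference_max: int = 3
    defined: bool = True

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (4,):
            raise ValueError("fractions must be length 4 (me0..me3)")
        if self.reference_max not in (2, 3):
            raise ValueError("reference_max must be 2 or 3")
        if self.defined:
            if np.any(self.fractions < -1e-12):
                raise ValueError("fractions must be non-negative")
            if abs(self.fractions.sum() - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")

    @property
    def weighted_sum(self) -> float:
        return float(np.dot(np.arange(4), self.fractions))

    @property
    def methylation_fraction(self) -> float:
        if not self.defined:
            return float("nan")
        return 100.0 * self.weighted_sum / self.reference_max

    @property
    def over_reference(self) -> bool:
        return self.defined and self.weighted_sum > self.reference_max + 1e-12

    def as_dict(self) -> dict:
        return {
            **{f"p{i}": float(self.fractions[i]) for i in range(4)},
            "reference_max": self.reference_max,
            "methylation_fraction": self.methylation_fraction,
            "defined": self.defined,
        }


def extract_xic(trace: ChromatogramTrace, window: XICWindow):
    """Extract the ion chromatogram within a ppm window (and rt range).

    Observations with |mz - target|/target * 1e6 <= tol_ppm are retained;
    co-timed retained intensities are summed per retention time.  Returns
    (rt, intensity) arrays; both empty when nothing falls in the window.
    """
    if len(trace) == 0:
        return np.empty(0), np.empty(0)
    ppm_dev = np.abs(trace.mz - window.target_mz) / window.target_mz * 1e6
    mask = ppm_dev <= window.tol_ppm
    if window.rt_range is not None:
        lo, hi = window.rt_range
        mask &= (trace.rt >= lo) & (trace.rt <= hi)
    rt, inten = trace.rt[mask], trace.intensity[mask]
    if rt.size == 0:
        return rt, inten
    uniq, inverse = np.unique(rt, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, inten)
    return uniq, summed


def integrate_auc(rt: np.ndarray, intensity: np.ndarray) -> float:
    """Trapezoidal area under an intensity-vs-rt series; 0 for < 2 points."""
    rt = np.asarray(rt, float)
    intensity = np.asarray(intensity, float)
    if rt.size < 2:
        return 0.0
    return float(np.trapezoid(intensity, rt))


def state_fractions(quants: Sequence[SpeciesQuant], reference_max: int = 3) -> MethylationProfile:
    """Normalise per-state AUCs into fractions p0..p3.

    Missing states count as zero area; duplicate state labels are an
    error.  Zero total signal yields an explicitly undefined profile.
    """
    seen: dict[str, float] = {}
    for q in quants:
        if q.state_label in seen:
            raise ValueError(f"duplicate state label {q.state_label!r}")
        if q.state_label not in STATE_LABELS:
            raise ValueError(f"unknown state label {q.state_label!r}")
        seen[q.state_label] = q.auc
    aucs = np.array([seen.get(label, 0.0) for label in STATE_LABELS])
    total = aucs.sum()
    if total <= 0:
        return MethylationProfile(np.full(4, np.nan), reference_max, defined=False)
    return MethylationProfile(aucs / total, reference_max)


def methylation_fraction(profile: MethylationProfile, reference_max: int | None = None) -> float:
    """Weighted methylation fraction, percent of the reference maximum."""
    if reference_max is not None:
        if reference_max not in (2, 3):
            raise ValueError("reference_max must be 2 or 3")
        profile = MethylationProfile(profile.fractions, reference_max, profile.defined)
    return profile.methylation_fraction


def quantify_states(
    trace: ChromatogramTrace,
    targets: Sequence[PrmTarget],
    mode: str = "precursor",
    *,
    tol_ppm: float = 10.0,
    rt_range: Optional[tuple[float, float]] = None,
    fragments: Optional[dict[str, Sequence[float]]] = None,
) -> list[SpeciesQuant]:
    """Integrate each methylation state's signal from one trace.

    ``mode='precursor'`` integrates the precursor XIC per target;
    ``mode='fragment_sum'`` sums AUCs over the fragment m/z list supplied
    per state label in ``fragments``.  Precursor windows of different
    states must not collide at the given ppm tolerance.
    """
    if mode not in ("precursor", "fragment_sum"):
        raise ValueError(f"unknown mode {mode!r}")
    windows = {
        t.state_label: XICWindow(t.mz, tol_ppm, rt_range) for t in targets
    }
    labels = list(windows)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if windows[a].overlaps(windows[b]):
                raise ValueError(
                    f"XIC windows for states {a!r} and {b!r} collide at "
                    f"{tol_ppm} ppm"
                )
    quants = []
    for t in targets:
        if mode == "precursor":
            auc = integrate_auc(*extract_xic(trace, windows[t.state_label]))
        else:
            if fragments is None or t.state_label not in fragments:
                raise ValueError(
                    f"fragment_sum mode requires a fragment list for state "
                    f"{t.state_label!r}"
                )
            auc = sum(
                integrate_auc(*extract_xic(trace, XICWindow(fmz, tol_ppm, rt_range)))
                for fmz in fragments[t.state_label]
            )
        quants.append(SpeciesQuant(t.state_label, auc, source=mode))
    return quants
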