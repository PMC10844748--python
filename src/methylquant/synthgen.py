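"""Seeded synthetic-data generators with attached ground truth.

Every pipeline stage gets a generator that emulates the corresponding
experimental input at desk scale: chromatographic traces of co-eluting
methylation states (Gaussian elution, ppm-scale m/z jitter, additive
truncated-Gaussian noise) at controlled true stoichiometries; toy
two-chain complexes with planted crosslink distances and a hinged domain;
replicate group tables with specified effects; and 4PL dose-response
titrations.  Generators are pure functions of (spec, seed): the same seed
reproduces byte-identical output, and each generator returns its ground
truth alongside the data so recovery tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .masscalc import STATE_LABELS, PrmTarget, prm_series
from .quantify import ChromatogramTrace, MethylationProfile
from .stats import DoseResponse, GroupTable, four_pl
from .structcheck import (
    Atom,
    CrosslinkPair,
    DistanceResult,
    DomainRange,
    StructureModel,
)

__all__ = [
    "TraceSpec",
    "ToyComplexSpec",
    "simulate_trace",
    "simulate_complex",
    "simulate_groups",
    "simulate_dose_response",
]

# Study-condition defaults for synthetic traces: a 19-residue GluC-type
# peptide series monitored at z=3, eluting ~2 s wide on a short gradient,
# sampled every 0.5 s, with jitter well inside the 10 ppm window.
DEFAULT_SEQUENCE = "QGVPGDNVGFNVKNVSVKE"
DEFAULT_SITE = 13
DEFAULT_CHARGE = 3


@dataclass
class TraceSpec:
    """Specification of one synthetic targeted acquisition.

    ``abundances`` are the true relative amounts of me0..me3 (any
    non-negative scale; not all zero).  ``noise_sd`` is additive intensity
    noise (truncated at zero); the default peak amplitude is 1000 units per
    unit abundance, so noise_sd=10 with max abundance 1 gives SNR >= 100.
    """

    abundances: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
    sequence: str = DEFAULT_SEQUENCE
    site: int = DEFAULT_SITE
    charge: int = DEFAULT_CHARGE
    elution_center: float = 60.0  # s
    elution_width: float = 2.0  # Gaussian sigma, s
    rt_step: float = 0.5  # s between scans
    rt_span: float = 30.0  # s simulated either side of the center
    amplitude: float = 1000.0  # peak height per unit abundance
    noise_sd: float = 0.0
    mz_jitter_ppm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        ab = np.asarray(self.abundances, float)
        if ab.shape != (4,) or np.any(ab < 0) or ab.sum() == 0:
            raise ValueError("abundances must be 4 non-negative values, not all 0")
        if self.elution_width <= 0:
            raise ValueError("elution_width must be > 0")

    def true_profile(self, reference_max: int = 3) -> MethylationProfile:
        ab = np.asarray(self.abundances, float)
        return MethylationProfile(ab / ab.sum(), reference_max)


def simulate_trace(spec: TraceSpec) -> tuple[ChromatogramTrace, list[PrmTarget], MethylationProfile]:
    """Simulate a targeted acquisition of the four methylation states.

    Each state elutes as a Gaussian at its theoretical precursor m/z with
    per-scan ppm jitter and additive noise truncated at zero.  Returns the
    trace, the PRM targets used, and the ground-truth profile.
    """
    rng = np.random.default_rng(spec.seed)
    targets = prm_series(spec.sequence, spec.site, spec.charge)
    rt_grid = np.arange(
        spec.elution_center - spec.rt_span,
        spec.elution_center + spec.rt_span + spec.rt_step / 2,
        spec.rt_step,
    )
    rts, mzs, intens = [], [], []
    for target, abundance in zip(targets, spec.abundances):
        signal = spec.amplitude * abundance * np.exp(
            -0.5 * ((rt_grid - spec.elution_center) / spec.elution_width) ** 2
        )
        jitter = rng.normal(0.0, spec.mz_jitter_ppm, rt_grid.size) * 1e-6
        noise = rng.normal(0.0, spec.noise_sd, rt_grid.size) if spec.noise_sd else 0.0
        rts.append(rt_grid)
        mzs.append(target.mz * (1.0 + jitter))
        intens.append(np.maximum(signal + noise, 0.0))
    trace = ChromatogramTrace(
        np.concatenate(rts), np.concatenate(mzs), np.concatenate(intens),
        acquisition_id=f"synthetic-seed{spec.seed}",
    )
    return trace, targets, spec.true_profile()


@dataclass
class ToyComplexSpec:
    """A desk-scale two-chain scaffold with planted crosslink distances.

    Chain A carries two rigid domains separated by a hinge; chain B (the
    'enzyme') is a short rigid segment near domain 2.  ``crosslinks`` are
    (resnum_a, resnum_b, target_distance_A) planted exactly; ``hinge_angle``
    (degrees) is the domain-1 rotation applied in the emitted reference
    conformation.
    """

    n_domain1: int = 12
    n_domain2: int = 12
    n_chain_b: int = 10
    crosslinks: Sequence[tuple] = ((3, 2, 10.0), (8, 5, 29.9), (15, 8, 30.1))
    hinge_angle: float = 90.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.hinge_angle < 180:
            raise ValueError("hinge angle must be in (0, 180) degrees")
        n_a = self.n_domain1 + self.n_domain2
        for ra, rb, d in self.crosslinks:
            if not 1 <= ra <= n_a:
                raise ValueError(f"crosslink residue A{ra} outside chain A")
            if not 1 <= rb <= self.n_chain_b:
                raise ValueError(f"crosslink residue B{rb} outside chain B")
            if d <= 0:
                raise ValueError("planted distance must be > 0")


_CA_SPACING = 3.8  # A, idealised backbone


def _ca_atom(chain: str, resnum: int, xyz) -> Atom:
    return Atom(chain, resnum, "ALA", "CA", "C", tuple(float(v) for v in xyz))


def simulate_complex(
    spec: ToyComplexSpec,
) -> tuple[StructureModel, StructureModel, list[CrosslinkPair], list[DistanceResult]]:
    """Build (model, reference, pairs, expected) for structural tests.

    The model is 'open': chain A extended along x with domain 1 then
    domain 2, chain B placed so each planted crosslink distance holds
    exactly.  The reference differs only by rotating domain 1 about the
    hinge (y axis) by ``hinge_angle``; chain B and domain 2 are identical.
    Expected DistanceResults are evaluated against a 30 A limit by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_a = spec.n_domain1 + spec.n_domain2
    # zig-zag backbone (non-collinear, so each domain is a valid rigid body
    # for superposition) advancing along x
    a_xyz = [
        np.array([i * _CA_SPACING, 1.0 * (i % 2), 0.0]) for i in range(n_a)
    ]
    atoms_a = [_ca_atom("A", i + 1, p) for i, p in enumerate(a_xyz)]
    # chain B: parked on a zig-zag parallel to chain A, offset in z; planted
    # crosslink partners are then moved onto spheres around their chain-A
    # residue at the requested distance, each in a distinct direction.
    b_xyz = [
        np.array([(spec.n_domain1 + i) * _CA_SPACING, 1.0 * (i % 2), 50.0])
        for i in range(spec.n_chain_b)
    ]
    directions = []
    for k in range(len(spec.crosslinks)):
        theta = 2.0 * math.pi * (k + rng.uniform(0.2, 0.8)) / max(len(spec.crosslinks), 1)
        directions.append(np.array([0.0, math.sin(theta), abs(math.cos(theta)) + 0.2]))
    for (ra, rb, dist), direction in zip(spec.crosslinks, directions):
        unit = direction / np.linalg.norm(direction)
        b_xyz[rb - 1] = a_xyz[ra - 1] + dist * unit
    atoms_b = [_ca_atom("B", j + 1, p) for j, p in enumerate(b_xyz)]
    model = StructureModel(atoms_a + atoms_b)

    # reference conformation: rotate domain 1 about the hinge point (the
    # first residue of domain 2) around the y axis
    angle = math.radians(spec.hinge_angle)
    rot = np.array(
        [
            [math.cos(angle), 0.0, math.sin(angle)],
            [0.0, 1.0, 0.0],
            [-math.sin(angle), 0.0, math.cos(angle)],
        ]
    )
    hinge_point = np.array([spec.n_domain1 * _CA_SPACING, 0.0, 0.0])
    coords = model.coords.copy()
    d1_mask = np.array(
        [a.chain == "A" and a.resnum <= spec.n_domain1 for a in model.atoms]
    )
    coords[d1_mask] = (coords[d1_mask] - hinge_point) @ rot.T + hinge_point
    reference = model.with_coords(coords)

    pairs = [
        CrosslinkPair(("A", ra), ("B", rb)) for ra, rb, _ in spec.crosslinks
    ]
    expected = [
        DistanceResult(pair, float(d), d <= pair.max_distance, "open")
        for pair, (_, _, d) in zip(pairs, spec.crosslinks)
    ]
    return model, reference, pairs, expected


def domain_ranges(spec: ToyComplexSpec) -> tuple[DomainRange, DomainRange]:
    """(hinge, anchor) domain definitions matching simulate_complex output."""
    hinge = DomainRange("A", ((1, spec.n_domain1),), "D1")
    anchor = DomainRange(
        "A", ((spec.n_domain1 + 1, spec.n_domain1 + spec.n_domain2),), "D2+D3"
    )
    return hinge, anchor


def simulate_groups(
    means: dict, sd: float, n: int, seed: int = 0, control_label: Optional[str] = None
) -> GroupTable:
    """Normal replicate tables: one group per entry of ``means``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    groups = {
        label: mu + rng.normal(0.0, sd, n) if sd > 0 else np.full(n, float(mu))
        for label, mu in means.items()
    }
    return GroupTable(groups, control_label)


def simulate_dose_response(
    params: tuple,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DoseResponse, tuple]:
    """4PL evaluations plus seeded Gaussian noise; ground truth attached."""
    bottom, top, ec50, hill = params
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    doses = np.asarray(doses, float)
    rng = np.random.default_rng(seed)
    y = four_pl(doses, bottom, top, ec50, hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, doses.size)
    return DoseResponse(doses, y), tuple(float(v) for v in params)
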