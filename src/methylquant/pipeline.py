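"""End-to-end orchestration: configuration, reports, coordinate utilities.

Composes the mass, quantification, statistics and structure modules into
two deterministic report-writing pipelines (methylation quantification
with optional group statistics; crosslink validation with optional
conformational remapping), plus the small gene-annotation arithmetic used
to re-derive a corrected start codon from genomic coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import quantify as q
from . import stats as st
from . import structcheck as sc
from .masscalc import PrmTarget

__all__ = [
    "PipelineConfig",
    "GeneCoordinatePair",
    "start_codon_offset",
    "run_quantification",
    "run_xl_validation",
]


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipelines, in one place.

    Round-trips losslessly through JSON (`save`/`load`).
    """

    tol_ppm: float = 10.0
    reference_max: int = 3
    crosslink_cutoff: float = 30.0
    polar_cutoff: float = 3.5
    pocket_cutoff: float = 4.5
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        for name in ("tol_ppm", "crosslink_cutoff", "polar_cutoff", "pocket_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.reference_max not in (2, 3):
            raise ValueError("reference_max must be 2 or 3")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GeneCoordinatePair:
    """Annotated vs corrected start coordinate of a gene (1-based, genomic)."""

    annotated_start: int
    corrected_start: int
    strand: str = "+"

    def __post_init__(self):
        if self.annotated_start <= 0 or self.corrected_start <= 0:
            raise ValueError("genomic coordinates are 1-based positive integers")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def start_codon_offset(pair: GeneCoordinatePair) -> tuple[int, int]:
    """Nucleotide offset of a corrected start site and the residue position
    the new start methionine occupies in the old annotation.

    The offset is measured in the direction of transcription and must be
    a non-negative whole number of codons; the returned residue position
    is offset/3 + 1 (position 1 is the annotated start methionine).
    """
    if pair.strand == "+":
        offset = pair.corrected_start - pair.annotated_start
    else:
        offset = pair.annotated_start - pair.corrected_start
    if offset < 0:
        raise ValueError(
            "corrected start lies upstream of the annotated start"
        )
    if offset % 3 != 0:
        raise ValueError(f"offset {offset} nt is out of frame (not divisible by 3)")
    return offset, offset // 3 + 1


def _profile_row(sample: str, profile: q.MethylationProfile) -> dict:
    return {"sample": sample, **profile.as_dict()}


def run_quantification(
    config: PipelineConfig,
    traces: dict,
    targets: Sequence[PrmTarget],
    groups: Optional[dict] = None,
    control_label: Optional[str] = None,
    mode: str = "precursor",
    fragments: Optional[dict] = None,
    out_dir: Optional[Path] = None,
) -> dict:
    """Quantify each trace into a methylation profile; compare groups.

    ``traces`` maps sample name -> ChromatogramTrace; ``groups`` (optional)
    maps group label -> list of sample names.  Writes profiles.tsv and
    report.json when ``out_dir`` is given.  Deterministic: identical inputs
    produce identical report bytes.
    """
    profiles = {}
    for sample in sorted(traces):
        quants = q.quantify_states(
            traces[sample], targets, mode, tol_ppm=config.tol_ppm,
            fragments=fragments,
        )
        profiles[sample] = q.state_fractions(quants, config.reference_max)

    report: dict = {
        "profiles": {s: p.as_dict() for s, p in profiles.items()},
        "reference_max": config.reference_max,
        "tol_ppm": config.tol_ppm,
    }

    if groups:
        missing = [
            s for members in groups.values() for s in members if s not in profiles
        ]
        if missing:
            raise KeyError(f"group members without traces: {missing}")
        values = {
            label: np.array(
                [profiles[s].methylation_fraction for s in members]
            )
            for label, members in groups.items()
        }
        table = st.GroupTable(values, control_label)
        stats_section: dict = {
            "group_means": {k: float(v.mean()) for k, v in values.items()}
        }
        if control_label is not None and len(values) > 1:
            res = st.anova_dunnett(table)
            stats_section.update(
                {
                    "anova_F": res.f_statistic,
                    "anova_p": res.p_value,
                    "control": control_label,
                    "dunnett_p": res.comparisons,
                    "stars": res.stars(),
                    "alpha": config.alpha,
                }
            )
        report["group_stats"] = stats_section

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [_profile_row(s, p) for s, p in sorted(profiles.items())]
        pd.DataFrame(rows).to_csv(
            out_dir / "profiles.tsv", sep="\t", index=False, float_format="%.6f"
        )
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


def read_crosslinks_tsv(path, default_cutoff: float = 30.0) -> list[sc.CrosslinkPair]:
    """Read a crosslink TSV (chain_a, res_a, chain_b, res_b[, max_dist])."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chain_a", "res_a", "chain_b", "res_b"}
    if not needed <= set(df.columns):
        raise ValueError(f"crosslink file needs columns {sorted(needed)}")
    pairs = []
    for row in df.itertuples(index=False):
        cutoff = float(getattr(row, "max_dist", default_cutoff))
        pairs.append(
            sc.CrosslinkPair(
                (str(row.chain_a), int(row.res_a)),
                (str(row.chain_b), int(row.res_b)),
                cutoff,
            )
        )
    return pairs


def run_xl_validation(
    config: PipelineConfig,
    model: sc.StructureModel,
    pairs: Sequence[sc.CrosslinkPair],
    reference: Optional[sc.StructureModel] = None,
    hinge: Optional[sc.DomainRange] = None,
    anchor: Optional[sc.DomainRange] = None,
    passenger_chains: Sequence[str] = (),
    out_dir: Optional[Path] = None,
) -> dict:
    """Evaluate crosslink restraints, optionally also after remapping onto
    a reference conformation; tabulate both conformations side by side."""
    results, summary = sc.evaluate_crosslinks(model, pairs, "open")
    report = {"open": _xl_section(results, summary)}

    if reference is not None:
        if hinge is None or anchor is None:
            raise ValueError("remapping requires hinge and anchor domain ranges")
        remapped = sc.remap_conformation(model, hinge, anchor, reference,
                                         passenger_chains)
        results_c, summary_c = sc.evaluate_crosslinks(remapped, pairs, "closed")
        report["closed"] = _xl_section(results_c, summary_c)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for conf, section in report.items():
            for entry in section["distances"]:
                rows.append({"conformation": conf, **entry})
        pd.DataFrame(rows).to_csv(
            out_dir / "crosslinks.tsv", sep="\t", index=False, float_format="%.3f"
        )
        (out_dir / "xl_summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


def _xl_section(results, summary) -> dict:
    return {
        "distances": [
            {
                "chain_a": r.pair.site_a[0],
                "res_a": r.pair.site_a[1],
                "chain_b": r.pair.site_b[0],
                "res_b": r.pair.site_b[1],
                "max_distance": r.pair.max_distance,
                "ca_distance": round(r.ca_distance, 3),
                "satisfied": bool(r.satisfied),
            }
            for r in results
        ],
        "n_satisfied": summary["n_satisfied"],
        "n_violated": summary["n_violated"],
        "errors": summary["errors"],
    }
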