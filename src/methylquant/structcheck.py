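"""Crosslink restraint evaluation, superposition and interface contacts.

Crosslinking-MS restraints are validated against a structural model by
measuring Calpha-Calpha distances between linked residues; for an
amine-reactive MS-cleavable linker such as DSSO the conventional limit is
30 A (inclusive).  Because multi-domain substrates can hinge between
conformations, a model can be remapped onto a reference conformation by
rigidly superposing each domain (plus any rigid passenger chains)
separately, then re-evaluating the restraints.  Interface analysis covers
polar (N/O...N/O) inter-chain contacts and the residues lining a binding
pocket around a probe side chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import gemmi

__all__ = [
    "StructureModel",
    "CrosslinkPair",
    "DistanceResult",
    "DomainRange",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "ca_distance",
    "evaluate_crosslinks",
    "superpose",
    "apply_transform",
    "remap_conformation",
    "polar_contacts",
    "pocket_residues",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    xyz: tuple


class StructureModel:
    """Heavy atoms of a (possibly multi-chain) model with author numbering.

    Addressing is by (chain id, residue number, atom name); coordinates
    are stored as an (n, 3) float array so rigid transforms are vectorised.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("empty structure model")
        self.atoms = atoms
        self.coords = np.array([a.xyz for a in atoms], dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        self._index: dict[tuple, int] = {}
        for i, a in enumerate(atoms):
            key = (a.chain, a.resnum, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom key {key}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        try:
            return self._index[(chain, int(resnum), name)]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} in residue {chain}:{resnum}"
            ) from None

    def xyz(self, chain: str, resnum: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(chain, resnum, name)]

    def has_atom(self, chain: str, resnum: int, name: str) -> bool:
        return (chain, int(resnum), name) in self._index

    def residues(self, chain: str) -> list[int]:
        seen = dict.fromkeys(a.resnum for a in self.atoms if a.chain == chain)
        return list(seen)

    def mask(self, chain: str, resnums: Optional[Iterable[int]] = None) -> np.ndarray:
        nums = None if resnums is None else set(int(r) for r in resnums)
        return np.array(
            [a.chain == chain and (nums is None or a.resnum in nums)
             for a in self.atoms],
            dtype=bool,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    mask: Optional[np.ndarray] = None) -> "StructureModel":
        coords = self.coords.copy()
        if mask is None:
            mask = np.ones(len(self), bool)
        coords[mask] = coords[mask] @ np.asarray(rotation).T + np.asarray(translation)
        return self.with_coords(coords)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, float)
        atoms = [
            Atom(a.chain, a.resnum, a.resname, a.name, a.element, tuple(c))
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(atoms)

    def copy(self) -> "StructureModel":
        return self.with_coords(self.coords)


@dataclass(frozen=True)
class CrosslinkPair:
    """A residue-residue restraint with its linker distance limit (A)."""

    site_a: tuple  # (chain, resnum)
    site_b: tuple
    max_distance: float = 30.0

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


@dataclass(frozen=True)
class DistanceResult:
    pair: CrosslinkPair
    ca_distance: float
    satisfied: bool
    conformation_label: str = "open"


@dataclass(frozen=True)
class DomainRange:
    """Residue intervals (inclusive, author numbering) of one rigid unit."""

    chain: str
    intervals: tuple  # ((start, end), ...)
    label: str = ""

    def __post_init__(self):
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for a, b in ivs:
            if a > b:
                raise ValueError(f"empty interval ({a}, {b}) in domain {self.label!r}")
        flat = sorted(ivs)
        for (a1, b1), (a2, b2) in zip(flat, flat[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping intervals in domain {self.label!r}")

    def resnums(self) -> list[int]:
        out = []
        for a, b in self.intervals:
            out.extend(range(a, b + 1))
        return out


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


def read_structure(path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Author chain ids and residue numbers are preserved; waters and hetero
    compounds are excluded; for alternate locations the highest-occupancy
    conformer is kept (ties resolved to the alphabetically first altloc).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"empty model in {path}")
    model = st[0]
    best: dict[tuple, tuple] = {}  # key -> (occupancy, altloc, Atom)
    order: list[tuple] = []
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            info = gemmi.find_tabulated_residue(residue.name)
            if info is not None and not info.is_amino_acid():
                continue  # waters/ligands/ions excluded; heavy-atom protein only
            for atom in residue:
                if atom.element == gemmi.Element("H"):
                    continue
                key = (chain.name, residue.seqid.num, atom.name)
                altloc = atom.altloc if atom.altloc not in ("", "\x00") else "A"
                cand = (
                    atom.occ,
                    altloc,
                    Atom(chain.name, residue.seqid.num, residue.name, atom.name,
                         atom.element.name, (atom.pos.x, atom.pos.y, atom.pos.z)),
                )
                if key not in best:
                    best[key] = cand
                    order.append(key)
                else:
                    occ, alt, _ = best[key]
                    if cand[0] > occ or (cand[0] == occ and cand[1] < alt):
                        best[key] = cand
    atoms = [best[k][2] for k in order]
    if not atoms:
        raise ValueError(f"no protein atoms found in {path}")
    return StructureModel(atoms)


def write_structure(model: StructureModel, path) -> None:
    """Write the model as a minimal single-model PDB file."""
    st = gemmi.Structure()
    st.name = "methylquant"
    md = gemmi.Model("1")
    for chain_name in model.chains:
        chain = gemmi.Chain(chain_name)
        current = None
        for atom, xyz in zip(model.atoms, model.coords):
            if atom.chain != chain_name:
                continue
            if current is None or current.seqid.num != atom.resnum:
                res = gemmi.Residue()
                res.name = atom.resname
                res.seqid = gemmi.SeqId(atom.resnum, " ")
                chain.add_residue(res)
                current = chain[-1]
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*xyz)
            ga.occ = 1.0
            current.add_atom(ga)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def ca_distance(model: StructureModel, site_a: tuple, site_b: tuple) -> float:
    """Euclidean Calpha-Calpha distance (A) between two residues."""
    coords = []
    for chain, resnum in (site_a, site_b):
        if not model.has_atom(chain, resnum, "CA"):
            raise KeyError(f"residue {chain}:{resnum} has no CA atom")
        coords.append(model.xyz(chain, resnum, "CA"))
    return float(np.linalg.norm(coords[0] - coords[1]))


def evaluate_crosslinks(
    model: StructureModel,
    pairs: Sequence[CrosslinkPair],
    conformation_label: str = "open",
) -> tuple[list[DistanceResult], dict]:
    """Evaluate each restraint; boundary is inclusive (d <= limit satisfies).

    Unresolvable sites are collected into the summary's ``errors`` list
    rather than silently dropped.
    """
    results = []
    errors = []
    for pair in pairs:
        try:
            d = ca_distance(model, pair.site_a, pair.site_b)
        except KeyError as exc:
            errors.append(f"{pair.site_a}-{pair.site_b}: {exc}")
            continue
        results.append(
            DistanceResult(pair, d, d <= pair.max_distance, conformation_label)
        )
    summary = {
        "conformation": conformation_label,
        "n_evaluated": len(results),
        "n_satisfied": sum(r.satisfied for r in results),
        "n_violated": sum(not r.satisfied for r in results),
        "errors": errors,
    }
    return results, summary


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping mobile onto reference (SVD)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def _paired_ca(
    mobile: StructureModel,
    reference: StructureModel,
    chain_mobile: str,
    chain_reference: str,
    resnums: Optional[Iterable[int]] = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    mob_res = set(mobile.residues(chain_mobile))
    ref_res = set(reference.residues(chain_reference))
    common = sorted(mob_res & ref_res)
    if resnums is not None:
        wanted = set(int(r) for r in resnums)
        common = [r for r in common if r in wanted]
    common = [
        r for r in common
        if mobile.has_atom(chain_mobile, r, "CA")
        and reference.has_atom(chain_reference, r, "CA")
    ]
    if not common:
        return np.empty((0, 3)), np.empty((0, 3)), []
    mcoords = np.array([mobile.xyz(chain_mobile, r, "CA") for r in common])
    rcoords = np.array([reference.xyz(chain_reference, r, "CA") for r in common])
    return mcoords, rcoords, common


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    chain: str,
    resnums: Optional[Iterable[int]] = None,
    reference_chain: Optional[str] = None,
) -> SuperpositionResult:
    """Kabsch Calpha superposition, pairing by residue-number intersection."""
    mcoords, rcoords, common = _paired_ca(
        mobile, reference, chain, reference_chain or chain, resnums
    )
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 paired CA atoms for superposition, got {len(common)}"
        )
    spread = np.linalg.svd(mcoords - mcoords.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-8:
        raise ValueError("degenerate (collinear) atom selection")
    rot, trans, rmsd = _kabsch(mcoords, rcoords)
    return SuperpositionResult(rot, trans, rmsd, len(common))


def apply_transform(model: StructureModel, result: SuperpositionResult,
                    mask: Optional[np.ndarray] = None) -> StructureModel:
    return model.transformed(result.rotation, result.translation, mask)


def remap_conformation(
    model: StructureModel,
    hinge_domain: DomainRange,
    anchor_domain: DomainRange,
    reference: StructureModel,
    passenger_chains: Sequence[str] = (),
) -> StructureModel:
    """Remap a hinged model onto a reference conformation.

    The anchor domain (plus any passenger chains, e.g. a bound enzyme that
    stays rigid with it) is superposed onto the reference's anchor; the
    hinge domain is then independently superposed onto the reference's
    hinge placement.  Within each rigid unit internal geometry is
    untouched, so re-running against the same reference is a no-op.
    """
    anchor_fit = superpose(model, reference, anchor_domain.chain,
                           anchor_domain.resnums())
    hinge_fit = superpose(model, reference, hinge_domain.chain,
                          hinge_domain.resnums())

    hinge_nums = set(hinge_domain.resnums())
    hinge_mask = np.array(
        [a.chain == hinge_domain.chain and a.resnum in hinge_nums
         for a in model.atoms],
        dtype=bool,
    )
    # everything that is not the hinge moves rigidly with the anchor
    anchor_mask = ~hinge_mask
    for ch in passenger_chains:
        anchor_mask |= model.mask(ch)

    coords = model.coords.copy()
    coords[anchor_mask] = (
        coords[anchor_mask] @ anchor_fit.rotation.T + anchor_fit.translation
    )
    coords[hinge_mask] = (
        coords[hinge_mask] @ hinge_fit.rotation.T + hinge_fit.translation
    )
    return model.with_coords(coords)


def _pairwise_min(
    model: StructureModel, idx_a: Sequence[int], idx_b: Sequence[int]
) -> dict:
    """Per residue pair, the closest atom pair between two atom index sets."""
    out: dict[tuple, tuple] = {}
    ca = model.coords[list(idx_a)]
    cb = model.coords[list(idx_b)]
    if not len(ca) or not len(cb):
        return out
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    for i, ia in enumerate(idx_a):
        aa = model.atoms[ia]
        for j, ib in enumerate(idx_b):
            ab = model.atoms[ib]
            key = ((aa.chain, aa.resnum), (ab.chain, ab.resnum))
            dist = float(d[i, j])
            if key not in out or dist < out[key][0]:
                out[key] = (dist, aa.name, ab.name)
    return out


def polar_contacts(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 3.5
) -> list[dict]:
    """Inter-chain polar contacts: N/O atoms of one chain within cutoff of
    N/O atoms of the other; one entry per residue pair (closest atom pair)."""
    if chain_a == chain_b:
        raise ValueError("polar_contacts requires two distinct chains")
    idx_a = [i for i, a in enumerate(model.atoms)
             if a.chain == chain_a and a.element in ("N", "O")]
    idx_b = [i for i, a in enumerate(model.atoms)
             if a.chain == chain_b and a.element in ("N", "O")]
    pairs = _pairwise_min(model, idx_a, idx_b)
    contacts = []
    for ((ca_, ra), (cb_, rb)), (dist, na, nb) in sorted(
        pairs.items(), key=lambda kv: kv[1][0]
    ):
        if dist <= cutoff:
            contacts.append({
                "residue_a": (ca_, ra), "residue_b": (cb_, rb),
                "atom_a": na, "atom_b": nb, "distance": dist,
            })
    return contacts


def pocket_residues(
    model: StructureModel, probe: tuple, cutoff: float = 4.5
) -> list[dict]:
    """Partner-chain residues with any heavy atom within cutoff of the probe
    residue's side-chain heavy atoms (Gly probed via its CA), sorted by
    minimal distance."""
    probe_chain, probe_resnum = probe[0], int(probe[1])
    probe_idx = [
        i for i, a in enumerate(model.atoms)
        if a.chain == probe_chain and a.resnum == probe_resnum
        and a.name not in _BACKBONE
    ]
    if not probe_idx:
        probe_idx = [
            i for i, a in enumerate(model.atoms)
            if a.chain == probe_chain and a.resnum == probe_resnum
            and a.name == "CA"
        ]
    if not probe_idx:
        raise KeyError(f"probe residue {probe_chain}:{probe_resnum} not in model")
    partner_idx = [i for i, a in enumerate(model.atoms) if a.chain != probe_chain]
    pairs = _pairwise_min(model, probe_idx, partner_idx)
    per_residue: dict[tuple, float] = {}
    for ((_, _), res_b), (dist, _, _) in pairs.items():
        if res_b not in per_residue or dist < per_residue[res_b]:
            per_residue[res_b] = dist
    hits = [
        {"residue": res, "min_distance": dist}
        for res, dist in per_residue.items() if dist <= cutoff
    ]
    hits.sort(key=lambda h: h["min_distance"])
    return hits
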