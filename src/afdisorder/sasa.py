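"""Solvent accessible surface area (Shrake-Rupley) and relative accessibility.

The engine rolls a probe sphere (default 1.4 A) over the van der Waals
surface by sampling each atom's solvent-expanded sphere on a golden-spiral
lattice and counting sample points that fall outside every neighbouring
atom's expanded sphere.  Per-residue ASA is the sum over the residue's heavy
atoms; RSA divides by the maximum accessibility of X in an extended
Gly-X-Gly tripeptide and clamps to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InputError
from .structure_io import ResidueRecord, StructureModel

#: protein van der Waals radii, A (C/N/O/S cover AlphaFold heavy atoms)
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_FALLBACK_RADIUS = 1.8
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 100

_HYDROGENS = frozenset({"H", "D"})


@dataclass
class RadiiSet:
    """Element -> vdW radius mapping with a documented fallback."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    probe_radius: float = DEFAULT_PROBE_RADIUS
    fallback: float = DEFAULT_FALLBACK_RADIUS

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.fallback <= 0:
            raise ConfigurationError("van der Waals radii must be positive")
        if self.probe_radius < 0:
            raise ConfigurationError("probe radius must be non-negative")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.fallback)


def golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i          # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n                   # midpoint z stratification
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def shrake_rupley(coords: np.ndarray,
                  radii: np.ndarray,
                  probe_radius: float = DEFAULT_PROBE_RADIUS,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom SASA in A^2.

    Parameters
    ----------
    coords:
        (n_atoms, 3) coordinates in A.
    radii:
        per-atom van der Waals radii in A.
    n_points:
        sphere sample count (>= 2); accuracy improves roughly as 1/n.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise InputError("coords must be a non-empty (n, 3) array")
    if not np.isfinite(coords).all():
        raise InputError("coordinates must be finite")
    if n_points < 2:
        raise ConfigurationError("n_points must be >= 2")
    if radii.shape != (coords.shape[0],):
        raise InputError("radii must align with coords")

    expanded = radii + probe_radius
    points = golden_spiral(n_points)
    tree = cKDTree(coords)
    max_exp = expanded.max()
    sasa = np.empty(len(coords))
    for i in range(len(coords)):
        r_i = expanded[i]
        # neighbours within r_i + r_j (+2*probe already folded into expanded)
        cand = tree.query_ball_point(coords[i], r_i + max_exp)
        nbrs = [j for j in cand if j != i and
                np.dot(coords[j] - coords[i], coords[j] - coords[i])
                < (r_i + expanded[j]) ** 2]
        if not nbrs:
            sasa[i] = 4.0 * np.pi * r_i * r_i
            continue
        sphere = coords[i] + r_i * points
        d2 = ((sphere[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
        exposed = (d2 >= (expanded[nbrs] ** 2)[None, :]).all(axis=1)
        sasa[i] = exposed.mean() * 4.0 * np.pi * r_i * r_i
    return sasa


def residue_asa(atom_sasa: np.ndarray,
                residue_index: np.ndarray,
                elements: np.ndarray | None = None,
                n_residues: int | None = None) -> np.ndarray:
    """Sum per-atom SASA into per-residue ASA, excluding hydrogens.

    ``residue_index`` assigns each atom to a 0-based residue slot.
    """
    atom_sasa = np.asarray(atom_sasa, dtype=float)
    residue_index = np.asarray(residue_index, dtype=int)
    keep = np.ones(len(atom_sasa), dtype=bool)
    if elements is not None:
        keep = ~np.isin(np.char.upper(np.asarray(elements, dtype=str)),
                        list(_HYDROGENS))
    n = n_residues if n_residues is not None else int(residue_index.max()) + 1
    return np.bincount(residue_index[keep], weights=atom_sasa[keep],
                       minlength=n)


# ---------------------------------------------------------------------------
# normalisation

def _max_asa_from_biopython(dialect: str) -> dict[str, float]:
    # Gly-X-Gly maximum accessibilities shipped with Biopython's PDB module
    from Bio.PDB.DSSP import residue_max_acc
    import gemmi

    key = {"sander": "Sander", "wilke": "Wilke", "miller": "Miller"}.get(
        dialect.lower())
    if key is None:
        raise ConfigurationError(
            f"unknown max-ASA dialect {dialect!r} (sander, wilke, miller)")
    table = {}
    for three, value in residue_max_acc[key].items():
        info = gemmi.find_tabulated_residue(three)
        if info is not None and info.is_amino_acid():
            table[info.one_letter_code.upper()] = float(value)
    return table


@dataclass
class MaxAsaTable:
    """One-letter amino acid -> max ASA of X in extended Gly-X-Gly (A^2)."""

    values: dict[str, float]
    dialect: str = "custom"

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ConfigurationError(
                f"max-ASA table missing amino acids: {sorted(missing)}")
        if any(v <= 0 for v in self.values.values()):
            raise ConfigurationError("max-ASA values must be positive")

    @classmethod
    def from_dialect(cls, dialect: str = "sander") -> "MaxAsaTable":
        return cls(_max_asa_from_biopython(dialect), dialect=dialect)

    def max_asa(self, aa: str) -> float:
        # unknown residues use the glycine maximum (conservative: glycine has
        # the smallest side chain, so RSA is not underestimated)
        return self.values.get(aa.upper(), self.values["G"])


def relative_accessibility(asa: float | np.ndarray,
                           aa: str,
                           table: MaxAsaTable) -> float | np.ndarray:
    """RSA = min(1, asa / max_asa[aa]); clamped so downstream scores stay
    in [0, 1]."""
    return np.minimum(1.0, np.asarray(asa, dtype=float) / table.max_asa(aa))


# ---------------------------------------------------------------------------
# model-level orchestration

def annotate_accessibility(model: StructureModel,
                           records: list[ResidueRecord],
                           chain: str | None = None,
                           radii: RadiiSet | None = None,
                           n_points: int = DEFAULT_N_POINTS,
                           max_asa: MaxAsaTable | None = None) -> list[ResidueRecord]:
    """Fill the asa/rsa fields of a residue table in place.

    SASA is computed over *all* chains of the model (inter-chain occlusion
    counts), then aggregated over the residues of the requested chain.
    """
    radii = radii or RadiiSet()
    max_asa = max_asa or MaxAsaTable.from_dialect("sander")
    coords, atom_radii, elements, res_idx = [], [], [], []
    target = model.chain(chain)
    slot = {}
    for ch in model.chains:
        for res in ch.residues:
            if ch is target:
                slot[id(res)] = len(slot)
            for atom in res.atoms:
                coords.append(atom.coord)
                atom_radii.append(radii.radius(atom.element))
                elements.append(atom.element)
                res_idx.append(slot.get(id(res), -1))
    atom_sasa = shrake_rupley(np.array(coords), np.array(atom_radii),
                              probe_radius=radii.probe_radius,
                              n_points=n_points)
    res_idx = np.asarray(res_idx)
    in_chain = res_idx >= 0
    per_res = residue_asa(atom_sasa[in_chain], res_idx[in_chain],
                          elements=np.asarray(elements)[in_chain],
                          n_residues=len(records))
    for rec, asa in zip(records, per_res):
        rec.asa = float(asa)
        rec.rsa = float(relative_accessibility(asa, rec.aa, max_asa))
    return records


# ---------------------------------------------------------------------------
# DSSP adapter

def read_dssp_acc(path) -> list[tuple[str, int, str, float]]:
    """Read per-residue absolute accessibility (ACC) from classic DSSP output.

    Returns (chain, residue number, one-letter aa, ACC in A^2) tuples; an
    alternative ASA source for parity studies against DSSP-based pipelines.
    """
    out = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 39:
                continue
            if line[13] == "!":       # chain break marker
                continue
            try:
                num = int(line[5:10])
                acc = float(line[34:38])
            except ValueError:
                continue
            out.append((line[11].strip(), num, line[13], acc))
    if not out:
        raise InputError(f"{path}: no residue ACC rows found (not DSSP output?)")
    return out
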