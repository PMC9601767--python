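"""Read AlphaFold-style PDB/mmCIF models and the tool's tabular formats.

AlphaFoldDB model files store the per-residue pLDDT confidence (0-100) in
the B-factor / isotropic-displacement column; this module parses models into
lightweight residue tables and reads/writes the CAID-style reference and
prediction dialects plus the per-residue TSV report.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    ConsistencyError,
    EmptyModelError,
    FormatError,
    InputError,
)

UNKNOWN = -1  #: reference label for residues excluded from evaluation

#: variants, in canonical output order
VARIANTS = ("pLDDT", "RSA", "Bind")


@dataclass
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    b_factor: float
    occupancy: float = 1.0


@dataclass
class Residue:
    position: int          # residue number from the file, 1-based
    name: str              # 3-letter residue name
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """A parsed structure: ordered chains of protein residues with atoms.

    Hetero/water records are excluded at parse time and alternate locations
    are resolved to the highest-occupancy conformer, so every atom here is a
    single protein heavy (or hydrogen) atom carrying a B-factor.
    """

    target_id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str | None = None) -> Chain:
        if chain_id is None:
            return self.chains[0]
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"chain {chain_id!r} not present in model "
                       f"{self.target_id!r} (chains: "
                       f"{[c.chain_id for c in self.chains]})")


@dataclass
class ResidueRecord:
    """One residue of a model: identity, confidence and accessibility."""

    position: int
    aa: str
    plddt_percent: float
    asa: float | None = None   # absolute accessibility, A^2
    rsa: float | None = None   # relative accessibility in [0, 1]


@dataclass
class ReferenceTrack:
    """Per-residue ground-truth labels: 1 positive, 0 negative, -1 unknown."""

    target_id: str
    sequence: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.sequence):
            raise ConsistencyError(
                f"{self.target_id}: {len(self.labels)} labels for "
                f"{len(self.sequence)} residues")


@dataclass
class PredictionTrack:
    """Per-residue continuous scores in [0,1] plus binary calls."""

    target_id: str
    variant: str
    scores: np.ndarray
    calls: np.ndarray

    @classmethod
    def from_scores(cls, target_id: str, variant: str,
                    scores: np.ndarray, threshold: float) -> "PredictionTrack":
        scores = np.asarray(scores, dtype=float)
        # call rule: score >= threshold -> positive (ties are positive)
        calls = (scores >= threshold).astype(np.int8)
        return cls(target_id, variant, scores, calls)

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# structure parsing

_PDB_RECORDS = ("ATOM  ", "HETATM")


def _sniff_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    for line in head.splitlines():
        if line[:6] in _PDB_RECORDS or line.startswith(("HEADER", "MODEL")):
            return "pdb"
    raise FormatError(f"cannot determine structure format of {path}")


def _check_pdb_bfactor(path: Path) -> None:
    """pLDDT lives in PDB columns 61-66; refuse files that lack them."""
    saw_atom = False
    with open(path) as fh:
        for line in fh:
            if line[:6] in _PDB_RECORDS:
                saw_atom = True
                if len(line.rstrip("\n")) < 66 or not line[60:66].strip():
                    raise FormatError(
                        f"{path}: ATOM record without a B-factor value; "
                        "pLDDT in the B-factor column is mandatory input")
    if not saw_atom:
        raise EmptyModelError(f"{path}: no ATOM/HETATM records")


def _read_mmcif(path: Path) -> gemmi.Structure:
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:
        raise FormatError(f"{path}: not readable as mmCIF: {exc}") from exc
    if not block.find_loop("_atom_site.B_iso_or_equiv"):
        raise FormatError(
            f"{path}: _atom_site loop lacks B_iso_or_equiv; "
            "pLDDT in the isotropic-displacement column is mandatory input")
    return gemmi.make_structure_from_block(block)


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        else:
            key = (atom.occ, -ord(atom.altloc or "\0"))
            prev_key = (prev.occ, -ord(prev.altloc or "\0"))
            if key > prev_key:
                by_name[atom.name] = atom
    # preserve file order of first appearance
    seen, out = set(), []
    for atom in residue:
        if atom.name not in seen:
            seen.add(atom.name)
            out.append(by_name[atom.name])
    return out


def from_gemmi(st: gemmi.Structure, target_id: str | None = None) -> StructureModel:
    """Convert a gemmi structure (first model) to a StructureModel.

    Hetero records (waters, ligands) are dropped; altlocs resolved.
    """
    model = StructureModel(target_id or st.name or "model")
    if len(st) == 0:
        raise EmptyModelError(f"{model.target_id}: structure has no models")
    for gchain in st[0]:
        chain = Chain(gchain.name)
        for gres in gchain:
            if gres.het_flag != "A":
                continue  # HETATM: waters, ligands, modified hetero groups
            res = Residue(gres.seqid.num, gres.name)
            for atom in _resolve_altlocs(gres):
                res.atoms.append(Atom(
                    name=atom.name,
                    element=atom.element.name,
                    coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                    b_factor=round(atom.b_iso, 4),  # gemmi stores float32
                    occupancy=atom.occ,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise EmptyModelError(
            f"{model.target_id}: no protein (ATOM) residues in structure")
    return model


def parse_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF model file, preserving per-atom B-factors.

    Parameters
    ----------
    path:
        Structure file. ``format`` may be ``pdb``, ``mmcif`` or ``auto``
        (extension, then content sniffing).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"structure file not found: {path}")
    fmt = format if format != "auto" else _sniff_format(path)
    if fmt == "pdb":
        _check_pdb_bfactor(path)
        try:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        except Exception as exc:
            raise FormatError(f"{path}: not readable as PDB: {exc}") from exc
    elif fmt == "mmcif":
        st = _read_mmcif(path)
    else:
        raise InputError(f"unknown format {fmt!r} (use pdb, mmcif or auto)")
    return from_gemmi(st, target_id=path.stem)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid() and info.is_standard():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def residue_table(model: StructureModel,
                  chain: str | None = None) -> list[ResidueRecord]:
    """One ResidueRecord per residue of a chain (default: first chain).

    pLDDT is taken from the CA atom's B-factor; when CA is absent the mean
    over the residue's atoms is used (AlphaFoldDB writes identical values on
    every atom, so the rule only matters for hand-made inputs).
    """
    ch = model.chain(chain)
    records = []
    for res in ch.residues:
        ca = next((a for a in res.atoms if a.name == "CA"), None)
        if ca is not None:
            plddt = ca.b_factor
        else:
            plddt = float(np.mean([a.b_factor for a in res.atoms]))
        records.append(ResidueRecord(res.position, _one_letter(res.name), plddt))
    return records


# ---------------------------------------------------------------------------
# tabular output

TSV_COLUMNS = ("target_id", "position", "aa", "plddt_percent",
               "score_pLDDT", "rsa_raw", "score_RSA", "score_Bind",
               "call_pLDDT", "call_RSA", "call_Bind")


def write_tsv(records: Sequence[ResidueRecord],
              tracks: dict[str, PredictionTrack],
              path: str | os.PathLike) -> None:
    """Write the per-residue report: identity, pLDDT, RSA and all scores.

    Scores are rendered with 3 decimals (Python float formatting, i.e.
    round-half-even on the decimal expansion).
    """
    for name in VARIANTS:
        if name not in tracks:
            raise ConsistencyError(f"missing prediction track {name!r}")
        if len(tracks[name]) != len(records):
            raise ConsistencyError(
                f"track {name}: {len(tracks[name])} scores for "
                f"{len(records)} residues")
    target_id = tracks["pLDDT"].target_id
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for i, rec in enumerate(records):
            rsa_raw = rec.rsa if rec.rsa is not None else float("nan")
            row = (
                target_id, str(rec.position), rec.aa,
                f"{rec.plddt_percent:.2f}",
                f"{tracks['pLDDT'].scores[i]:.3f}",
                f"{rsa_raw:.3f}",
                f"{tracks['RSA'].scores[i]:.3f}",
                f"{tracks['Bind'].scores[i]:.3f}",
                str(int(tracks["pLDDT"].calls[i])),
                str(int(tracks["RSA"].calls[i])),
                str(int(tracks["Bind"].calls[i])),
            )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# CAID dialects

_STATE_MAP = {"0": 0, "1": 1, "-": UNKNOWN}


def read_reference(path: str | os.PathLike) -> list[ReferenceTrack]:
    """Read a CAID-style reference file.

    Each record is three lines: a ``>``-prefixed target id, the amino-acid
    sequence, and a same-length state string over ``{0,1,-}`` where ``-``
    marks residues with unknown annotation.
    """
    tracks: list[ReferenceTrack] = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record {lines[i]!r}")
        target_id = lines[i][1:].split()[0]
        seq, states = lines[i + 1].strip(), lines[i + 2].strip()
        if len(states) != len(seq):
            raise FormatError(
                f"{path}: {target_id}: state string length {len(states)} != "
                f"sequence length {len(seq)}")
        try:
            labels = np.array([_STATE_MAP[c] for c in states], dtype=np.int8)
        except KeyError as exc:
            raise FormatError(
                f"{path}: {target_id}: invalid state character {exc}") from exc
        tracks.append(ReferenceTrack(target_id, seq, labels))
        i += 3
    return tracks


def write_reference(tracks: Iterable[ReferenceTrack],
                    path: str | os.PathLike) -> None:
    rev = {0: "0", 1: "1", UNKNOWN: "-"}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in tracks:
            states = "".join(rev[int(v)] for v in t.labels)
            fh.write(f">{t.target_id}\n{t.sequence}\n{states}\n")


def write_caid_prediction(track: PredictionTrack, sequence: str,
                          dest: str | os.PathLike | io.TextIOBase) -> None:
    """Write one target in the CAID submission dialect.

    A ``>``-header line, then one line per residue with 1-based position,
    amino acid, 3-decimal score and the binary call.
    """
    if len(track) != len(sequence):
        raise ConsistencyError(
            f"{track.target_id}: {len(track)} scores for "
            f"{len(sequence)} residues")
    own = not hasattr(dest, "write")
    fh = open(dest, "w", encoding="utf-8", newline="\n") if own else dest
    try:
        fh.write(f">{track.target_id}\n")
        for i, aa in enumerate(sequence):
            fh.write(f"{i + 1}\t{aa}\t{track.scores[i]:.3f}"
                     f"\t{int(track.calls[i])}\n")
    finally:
        if own:
            fh.close()


def read_caid_predictions(path: str | os.PathLike,
                          variant: str = "pLDDT") -> list[PredictionTrack]:
    """Read CAID prediction file(s): the inverse of write_caid_prediction."""
    tracks: list[PredictionTrack] = []
    target_id, scores, calls = None, [], []

    def flush():
        if target_id is not None:
            tracks.append(PredictionTrack(
                target_id, variant,
                np.array(scores, dtype=float),
                np.array(calls, dtype=np.int8)))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            target_id, scores, calls = line[1:].split()[0], [], []
            continue
        parts = line.split("\t")
        if target_id is None or len(parts) < 3:
            raise FormatError(f"{path}: malformed prediction line {raw!r}")
        scores.append(float(parts[2]))
        calls.append(int(parts[3]) if len(parts) > 3 else 0)
    flush()
    return tracks
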