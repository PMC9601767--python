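import numpy as np
import pytest

import afdisorder as afd
from afdisorder.synthetic_structures import Segment, SyntheticSpec, build_model

# --- hand-written 3-residue fixtures (B-factors 90.0 / 50.0 / 30.0) --------

PDB_3RES = """\
ATOM      1  N   GLY A   1       0.000   0.800   0.000  1.00 90.00           N
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00 90.00           C
ATOM      3  C   GLY A   1       2.000   0.800   0.000  1.00 90.00           C
ATOM      4  N   ALA A   2       3.000   0.000   0.000  1.00 50.00           N
ATOM      5  CA  ALA A   2       4.000   0.800   0.000  1.00 50.00           C
ATOM      6  C   ALA A   2       5.000   0.000   0.000  1.00 50.00           C
ATOM      7  N   LYS A   3       6.000   0.800   0.000  1.00 30.00           N
ATOM      8  CA  LYS A   3       7.000   0.000   0.000  1.00 30.00           C
ATOM      9  C   LYS A   3       8.000   0.800   0.000  1.00 30.00           C
TER      10      LYS A   3
END
"""

MMCIF_3RES = """\
data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
ATOM 1 N N . GLY A 1 1 1 A 0.000 0.800 0.000 1.00 90.00
ATOM 2 C CA . GLY A 1 1 1 A 1.000 0.000 0.000 1.00 90.00
ATOM 3 C C . GLY A 1 1 1 A 2.000 0.800 0.000 1.00 90.00
ATOM 4 N N . ALA A 1 2 2 A 3.000 0.000 0.000 1.00 50.00
ATOM 5 C CA . ALA A 1 2 2 A 4.000 0.800 0.000 1.00 50.00
ATOM 6 C C . ALA A 1 2 2 A 5.000 0.000 0.000 1.00 50.00
ATOM 7 N N . LYS A 1 3 3 A 6.000 0.800 0.000 1.00 30.00
ATOM 8 C CA . LYS A 1 3 3 A 7.000 0.000 0.000 1.00 30.00
ATOM 9 C C . LYS A 1 3 3 A 8.000 0.800 0.000 1.00 30.00
"""


@pytest.fixture
def pdb_3res(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(PDB_3RES)
    return path


@pytest.fixture
def mmcif_3res(tmp_path):
    path = tmp_path / "tiny.cif"
    path.write_text(MMCIF_3RES)
    return path


# --- synthetic models -------------------------------------------------------

@pytest.fixture(scope="session")
def buried_core():
    """Compact high-confidence core: every score below every threshold."""
    spec = SyntheticSpec("core", [Segment(125, "collapsed-core", 95.0, "order")],
                         seed=3)
    model, refs = build_model(spec)
    return model, refs


@pytest.fixture(scope="session")
def exposed_chain():
    """Fully extended low-confidence chain: disorder, not binding."""
    spec = SyntheticSpec("ext", [Segment(30, "extended", 30.0, "disorder")],
                         seed=2)
    model, refs = build_model(spec)
    return model, refs


@pytest.fixture(scope="session")
def suite():
    """The seeded 20-target benchmark suite used by end-to-end tests."""
    return afd.benchmark_suite(20, seed=1)


@pytest.fixture(scope="session")
def suite_predictions(suite):
    preds = {t.spec.target_id: afd.predict(t.model) for t in suite}
    dis_refs = {t.spec.target_id: t.references["disorder"] for t in suite}
    bind_refs = {t.spec.target_id: t.references["binding"] for t in suite}
    return preds, dis_refs, bind_refs


# --- independent oracles ----------------------------------------------------

def mirrored_mean_oracle(values, window):
    """Brute-force windowed mean with reflection about the terminal element
    (no edge duplication), applied recursively for long overhangs."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    h = (window - 1) // 2

    def reflect(j):
        if n == 1:
            return 0
        period = 2 * n - 2
        j = j % period
        return period - j if j >= n else j

    return np.array([
        np.mean([values[reflect(i + k)] for k in range(-h, h + 1)])
        for i in range(n)
    ])


def auc_pair_oracle(scores, labels):
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def f1_bruteforce(scores, labels, threshold):
    calls = np.asarray(scores) >= threshold
    labels = np.asarray(labels)
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    return 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0


def fmax_bruteforce(scores, labels):
    cuts = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    return max(f1_bruteforce(scores, labels, t) for t in cuts)


def sasa_dense_oracle(coords, radii, probe=1.4, n=100_000, seed=0):
    """Independent dense-sampling SASA (random directions, not a lattice)."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * dirs
        exposed = np.ones(n, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= expanded[j] ** 2
        out[i] = exposed.mean() * 4 * np.pi * expanded[i] ** 2
    return out
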