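"""The three per-residue scores derived from a predicted structure model.

* ``pLDDT`` disorder: 1 - pLDDT/100.  Low model confidence tracks intrinsic
  disorder; the default decision threshold 0.312 corresponds to pLDDT below
  68.8%.
* ``RSA`` disorder: relative solvent accessibility averaged over a local
  window (default 25 residues, i.e. +/-12) centred on the residue, with
  mirrored indices near the termini.  Disordered regions form exposed
  "ribbons" around the folded core.
* ``Bind`` (conditional folding): equals the windowed RSA score when that is
  at most T, otherwise T + p*(1-T) with p the residue's pLDDT fraction.
  Residues that are simultaneously exposed and confidently modelled score
  high, the signature of disordered binding regions that fold on binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import sasa as sasa_mod
from . import structure_io as sio
from .errors import ConfigurationError, InputError
from .structure_io import PredictionTrack, ResidueRecord, StructureModel


@dataclass
class ScoreConfig:
    """All method constants.

    window:
        odd local-window length for RSA smoothing (25 = +/-12 residues).
    thr_plddt / thr_rsa / thr_bind:
        decision thresholds for the three score variants (calibrated by F1
        maximisation on the CAID DisProt / DisProt-binding references).
    T:
        branch point of the Bind score; defaults to thr_rsa.
    mirror:
        terminus handling of the window: ``reflect`` (mirror about the
        terminal residue without duplicating it) or ``edge`` (duplicate it).
    """

    window: int = 25
    thr_plddt: float = 0.312
    thr_rsa: float = 0.581
    thr_bind: float = 0.773
    T: float | None = None
    probe_radius: float = sasa_mod.DEFAULT_PROBE_RADIUS
    n_points: int = sasa_mod.DEFAULT_N_POINTS
    max_asa_dialect: str = "sander"
    mirror: str = "reflect"
    radii: dict[str, float] = field(
        default_factory=lambda: dict(sasa_mod.DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError(
                f"window must be odd and >= 1, got {self.window}")
        for name in ("thr_plddt", "thr_rsa", "thr_bind"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.T is None:
            self.T = self.thr_rsa
        if not 0.0 < self.T < 1.0:
            raise ConfigurationError(f"T={self.T} outside (0, 1)")
        if self.mirror not in ("reflect", "edge"):
            raise ConfigurationError(f"unknown mirror mode {self.mirror!r}")

    def threshold(self, variant: str) -> float:
        return {"pLDDT": self.thr_plddt, "RSA": self.thr_rsa,
                "Bind": self.thr_bind}[variant]

    def radii_set(self) -> sasa_mod.RadiiSet:
        return sasa_mod.RadiiSet(dict(self.radii),
                                 probe_radius=self.probe_radius)


def plddt_disorder(plddt_percent):
    """Disorder score 1 - pLDDT/100 for pLDDT on the 0-100 scale."""
    p = np.asarray(plddt_percent, dtype=float)
    if np.any(p < 0) or np.any(p > 100):
        raise InputError("pLDDT must lie in [0, 100]")
    out = 1.0 - p / 100.0
    return float(out) if out.ndim == 0 else out


def windowed_mean(values: Sequence[float], window: int,
                  mirror: str = "reflect") -> np.ndarray:
    """Centred moving average with mirrored termini.

    Out-of-range indices are reflected about the terminal element without
    duplicating it (-k -> +k, N-1+k -> N-1-k), recursively when the window
    overhangs the whole sequence.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise InputError("values must be a non-empty 1-D sequence")
    if window == 1:
        return values.copy()
    h = (window - 1) // 2
    mode = "reflect" if mirror == "reflect" else "edge"
    if values.size == 1:      # numpy cannot reflect a single element
        padded = np.full(window, values[0])
    else:
        padded = np.pad(values, h, mode=mode)
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def rsa_disorder(records: Sequence[ResidueRecord],
                 config: ScoreConfig | None = None) -> np.ndarray:
    """Windowed mean of per-residue RSA (requires the sasa stage)."""
    config = config or ScoreConfig()
    rsa = [rec.rsa for rec in records]
    if any(v is None for v in rsa):
        raise InputError("records lack rsa values; run the sasa stage first")
    return windowed_mean(np.array(rsa, dtype=float), config.window,
                         mirror=config.mirror)


def bind_score(rsa_score, plddt_percent, config: ScoreConfig | None = None):
    """Conditional-folding score.

    Equals ``rsa_score`` when rsa_score <= T; otherwise ``T + p*(1-T)`` with
    p = pLDDT/100 (the raw per-residue confidence, not window-smoothed).
    The rescaling keeps the output in [0, 1].
    """
    config = config or ScoreConfig()
    T = config.T
    rsa = np.asarray(rsa_score, dtype=float)
    p = np.asarray(plddt_percent, dtype=float) / 100.0
    out = np.where(rsa <= T, rsa, T + p * (1.0 - T))
    return float(out) if out.ndim == 0 else out


@dataclass
class Prediction:
    """Result of running the full pipeline on one model."""

    target_id: str
    records: list[ResidueRecord]
    tracks: dict[str, PredictionTrack]

    @property
    def sequence(self) -> str:
        return "".join(rec.aa for rec in self.records)


def predict(model: StructureModel,
            config: ScoreConfig | None = None,
            chain: str | None = None) -> Prediction:
    """Run residue extraction, SASA/RSA and all three scores on one model.

    Binary calls use the >= rule at each variant's threshold.  Deterministic:
    the same file and config always yield identical tracks.
    """
    config = config or ScoreConfig()
    records = sio.residue_table(model, chain=chain)
    sasa_mod.annotate_accessibility(
        model, records, chain=chain,
        radii=config.radii_set(), n_points=config.n_points,
        max_asa=sasa_mod.MaxAsaTable.from_dialect(config.max_asa_dialect))
    plddt = np.array([rec.plddt_percent for rec in records])
    s_plddt = plddt_disorder(plddt)
    s_rsa = rsa_disorder(records, config)
    s_bind = bind_score(s_rsa, plddt, config)
    tracks = {
        "pLDDT": PredictionTrack.from_scores(model.target_id, "pLDDT",
                                             s_plddt, config.thr_plddt),
        "RSA": PredictionTrack.from_scores(model.target_id, "RSA",
                                           s_rsa, config.thr_rsa),
        "Bind": PredictionTrack.from_scores(model.target_id, "Bind",
                                            s_bind, config.thr_bind),
    }
    return Prediction(model.target_id, records, tracks)


def load_config(path, base: ScoreConfig | None = None) -> ScoreConfig:
    """Read ``key = value`` overrides for ScoreConfig fields from a file."""
    base = base or ScoreConfig()
    overrides = {}
    casts = {"window": int, "n_points": int, "max_asa_dialect": str,
             "mirror": str}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}: expected key = value, "
                                         f"got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in ScoreConfig.__dataclass_fields__:
                raise ConfigurationError(f"{path}: unknown config key {key!r}")
            overrides[key] = casts.get(key, float)(value)
    return replace(base, **overrides)
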