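"""Synthetic feature tables with the study design and known ground truth.

The generator emulates the structure of the real experiment: 48 samples
(3 organs x 2 lines x 2 experiment blocks x 4 biological replicates),
log-normal biological noise around a feature-specific baseline, an
additive experiment-block shift, planted organ / line / organ-x-line
effects on configurable fractions of features, and rank-based censoring
of the lowest raw intensities to emulate a detection limit.  Every
planted effect is returned as ground truth so downstream sensitivity
and calibration are measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .featuretable import FeatureTable, LINES, ORGANS, canonical_design

__all__ = ["SimulationConfig", "EffectSpec", "simulate", "spike_library_features"]


@dataclass(frozen=True)
class SimulationConfig:
    n_features: int = 2000
    fraction_organ_affected: float = 0.2
    fraction_line_affected: float = 0.1
    fraction_interaction: float = 0.05
    organ_effect: float = 2.0        # log2 spread of organ shifts
    line_effect: float = 2.0         # |log2 FC| planted on Bd3-1
    interaction_effect: float = 2.0  # |log2| organ-specific line shift
    base_mean: float = 14.0          # log2 baseline intensity
    base_sd: float = 2.0             # between-feature baseline spread (log2)
    sigma_bio: float = 0.5           # replicate SD (log2)
    sigma_block: float = 0.25        # experiment-block SD (log2)
    lod_quantile: float = 0.05       # fraction of raw intensities censored
    planted_effect_threshold: float = 1.0  # |log2 FC| that defines a planted DAM
    library_fraction: float = 0.0    # fraction of features given library m/z
    spike_jitter_ppm: float = 3.0
    decoy_margin_ppm: float = 10.0
    annotation_tol_ppm: float = 5.0
    n_replicates: int = 4
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_organ_affected", "fraction_line_affected",
                     "fraction_interaction", "lod_quantile", "library_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_bio", "sigma_block", "base_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.spike_jitter_ppm > self.annotation_tol_ppm:
            raise ValueError(
                "spike_jitter_ppm exceeds annotation_tol_ppm: spiked features "
                "would fall outside the annotation window by construction")


@dataclass(frozen=True)
class EffectSpec:
    """Planted ground truth for one feature."""

    feature_id: str
    organ_shifts: dict          # organ -> log2 shift
    line_shift: float           # log2 shift applied to Bd3-1 in every organ
    interaction_shifts: dict    # organ -> extra log2 shift for Bd3-1
    is_planted_dam: dict = field(default_factory=dict)  # organ -> bool

    def line_difference(self, organ: str) -> float:
        """Total planted Bd3-1 minus Bd21 log2 difference in ``organ``."""
        return self.line_shift + self.interaction_shifts.get(organ, 0.0)


def _draw_mzs(cfg: SimulationConfig, rng: np.random.Generator, library):
    """Feature m/z values: library ions with ppm jitter, decoys >= margin away."""
    n = cfg.n_features
    n_spiked = int(round(cfg.library_fraction * n)) if library else 0
    lib_mz, lib_pol, spiked_ids = [], [], []
    if n_spiked:
        pool = [r for r in library if r.formula is not None]
        picks = rng.choice(len(pool), size=n_spiked, replace=n_spiked > len(pool))
        for k in picks:
            rec = pool[int(k)]
            jitter = rng.uniform(-cfg.spike_jitter_ppm, cfg.spike_jitter_ppm)
            lib_mz.append(rec.theoretical_mz * (1 + jitter * 1e-6))
            lib_pol.append(rec.polarity)
            spiked_ids.append(rec.compound_id)
    ref_masses = np.array(
        [r.theoretical_mz for r in library if r.formula is not None]
        if library else [], dtype=float)
    decoys, dec_pol = [], []
    while len(decoys) < n - n_spiked:
        cand = rng.uniform(100.0, 1000.0, size=2 * (n - n_spiked - len(decoys)) + 8)
        for mz in cand:
            if len(decoys) >= n - n_spiked:
                break
            if ref_masses.size and np.min(np.abs(ref_masses - mz) / ref_masses) * 1e6 < cfg.decoy_margin_ppm:
                continue
            decoys.append(mz)
            dec_pol.append("positive" if rng.random() < 0.5 else "negative")
    mzs = lib_mz + decoys
    pols = lib_pol + dec_pol
    spiked = spiked_ids + [""] * len(decoys)
    return np.asarray(mzs), pols, spiked


def simulate(cfg: SimulationConfig, library=None):
    """Generate a raw feature table and the planted ground truth.

    Returns ``(FeatureTable, list[EffectSpec])``; identical config and
    seed give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = canonical_design(n_replicates=cfg.n_replicates)
    n, m = cfg.n_features, len(design)

    organ_idx = np.array([ORGANS.index(o) for o in design["organ"]])
    is_bd31 = (design["line"] == LINES[1]).to_numpy()
    exp_idx = (design["experiment"] == "E2").to_numpy().astype(int)

    base = rng.normal(cfg.base_mean, cfg.base_sd, size=n)
    organ_affected = rng.random(n) < cfg.fraction_organ_affected
    line_affected = rng.random(n) < cfg.fraction_line_affected
    inter_affected = rng.random(n) < cfg.fraction_interaction

    organ_shifts = np.where(organ_affected[:, None],
                            rng.normal(0.0, cfg.organ_effect, size=(n, 3)), 0.0)
    signs = rng.choice([-1.0, 1.0], size=n)
    line_shift = np.where(line_affected, signs * cfg.line_effect, 0.0)
    inter_organ = rng.integers(0, 3, size=n)
    inter_sign = rng.choice([-1.0, 1.0], size=n)
    inter_shifts = np.zeros((n, 3))
    inter_shifts[np.arange(n), inter_organ] = np.where(
        inter_affected, inter_sign * cfg.interaction_effect, 0.0)

    block = rng.normal(0.0, cfg.sigma_block, size=n)  # +b in E1, -b in E2
    noise = rng.normal(0.0, cfg.sigma_bio, size=(n, m))

    log2_int = (base[:, None]
                + organ_shifts[:, organ_idx]
                + np.where(is_bd31[None, :], line_shift[:, None], 0.0)
                + np.where(is_bd31[None, :], inter_shifts[:, organ_idx], 0.0)
                + np.where(exp_idx[None, :] == 0, block[:, None], -block[:, None])
                + noise)
    raw = np.exp2(log2_int)

    if cfg.lod_quantile > 0:
        lod = np.quantile(raw, cfg.lod_quantile)
        raw = np.where(raw < lod, np.nan, raw)

    feature_ids = [f"F{i+1:05d}" for i in range(n)]
    mzs, pols, spiked = _draw_mzs(cfg, rng, library)
    features = pd.DataFrame({
        "feature_id": feature_ids,
        "mz": mzs,
        "rt": rng.uniform(0.5, 12.0, size=n),
        "polarity": pols,
    })
    features["spiked_compound"] = spiked
    intensities = pd.DataFrame(raw, index=pd.Index(feature_ids, name="feature_id"),
                               columns=design["sample_id"])
    table = FeatureTable(features, design, intensities, "raw")

    truth = []
    for i, fid in enumerate(feature_ids):
        spec = EffectSpec(
            feature_id=fid,
            organ_shifts={o: float(organ_shifts[i, j]) for j, o in enumerate(ORGANS)},
            line_shift=float(line_shift[i]),
            interaction_shifts={o: float(inter_shifts[i, j]) for j, o in enumerate(ORGANS)},
        )
        spec.is_planted_dam.update({
            o: abs(spec.line_difference(o)) > cfg.planted_effect_threshold
            for o in ORGANS})
        truth.append(spec)
    return table, truth


def spike_library_features(cfg: SimulationConfig, library) -> FeatureTable:
    """Simulate a table whose m/z axis mixes library ions and decoys.

    Convenience wrapper: equivalent to ``simulate`` with a non-zero
    ``library_fraction`` (which must be set in ``cfg``).
    """
    if not library:
        raise ValueError("library must be non-empty")
    if cfg.library_fraction <= 0:
        cfg = replace(cfg, library_fraction=0.2)
    table, _ = simulate(cfg, library=library)
    return table
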