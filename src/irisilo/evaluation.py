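"""Match-rate statistics and the leakage-attack experiment harness.

The basic statistic is the match rate m(d) = |{i : d_i <= d}| / M, the
empirical CDF of a score collection with an inclusive threshold.  Applied to
impostor scores it is the False Match Rate, to genuine scores the positive
match rate (FNMR = 1 - m(d)), and to intruder scores the Intruder Match Rate
IMR(d).  For a division scheme, the IMR of the strongest (r-type) attack is
that scheme's *risk of leakage*.

:func:`run_leakage_experiment` replays the whole attack pipeline on a
synthetic population: divide each subject's reference, leak one partial,
mount the configured attacks, score the attack probes against the original
reference (Leaked Template Not Replaced) or a fresh recapture of the same
subject (Leaked Template Replaced), under both metrics, and tabulate IMR per
(scheme, attack, size, metric, threshold) cell.  The run is a deterministic
function of the config's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import (
    UndefinedScoreError,
    hamming_distance,
    modified_hamming_distance,
)
from .division import (
    default_block_grid,
    divide_block,
    divide_r_dispersion,
    divide_z_dispersion,
)
from .intruder import (
    SnapshotSchedule,
    bagged_reconstruct,
    complementary_partial,
    occlusion_attack,
    reconstruct_rn,
    reconstruct_tn,
)
from .ising import IsingParams
from .templates import Template

__all__ = [
    "ScoreSet",
    "LeakageExperimentConfig",
    "LeakageResult",
    "match_rate",
    "imr",
    "fmr_fnmr_eer",
    "eer",
    "run_leakage_experiment",
    "DEFAULT_ATTACKS",
]

DEFAULT_ATTACKS = {
    "block": ("occlusion", "tn", "rn"),
    "r_dispersion": ("occlusion", "tn", "rn"),
    "z_dispersion": ("occlusion", "tn", "rn", "tn_k", "rn_k"),
}


@dataclass(frozen=True)
class ScoreSet:
    """A labeled collection of dissimilarity scores under one metric."""

    scores: np.ndarray
    label: str = "genuine"
    metric: str = "hd"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or len(scores) == 0:
            raise ValueError("a score set must be a nonempty 1-D collection")
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)


def _scores_of(s) -> np.ndarray:
    arr = s.scores if isinstance(s, ScoreSet) else np.asarray(s, dtype=float)
    if len(arr) == 0:
        raise ValueError("empty score collection")
    return arr


def match_rate(scores, d: float) -> float:
    """m(d): the fraction of scores at or below the threshold (inclusive)."""
    arr = _scores_of(scores)
    return float((arr <= d).mean())


def imr(intruder_scores, d: float) -> float:
    """Intruder Match Rate: m(d) over intruder scores.  For an r-type attack
    this is the division scheme's risk of leakage."""
    return match_rate(intruder_scores, d)


def eer(genuine, impostor, grid_step: float = 1e-3) -> float:
    """Equal Error Rate: the crossing of the empirical FMR and FNMR curves,
    linearly interpolated on a threshold grid."""
    g = _scores_of(genuine)
    i = _scores_of(impostor)
    ts = np.arange(0.0, 1.0 + grid_step, grid_step)
    fmr = np.array([(i <= t).mean() for t in ts])
    fnmr = np.array([(g > t).mean() for t in ts])
    diff = fmr - fnmr
    idx = int(np.argmax(diff >= 0))  # diff is -FNMR(0) <= 0 at t=0, rises to +1
    if idx == 0:
        return float((fmr[0] + fnmr[0]) / 2)
    d0, d1 = diff[idx - 1], diff[idx]
    w = 0.0 if d1 == d0 else -d0 / (d1 - d0)
    fmr_x = fmr[idx - 1] + w * (fmr[idx] - fmr[idx - 1])
    fnmr_x = fnmr[idx - 1] + w * (fnmr[idx] - fnmr[idx - 1])
    return float((fmr_x + fnmr_x) / 2)


def fmr_fnmr_eer(
    genuine: ScoreSet,
    impostor: ScoreSet,
    thresholds: Sequence[float] = (0.4, 0.431),
) -> tuple[pd.DataFrame, float]:
    """FMR/FNMR at each threshold plus the EER, as (table, eer).

    FMR and 1 - FNMR are the same functional (the match rate) applied to the
    impostor and genuine sets respectively.
    """
    if isinstance(genuine, ScoreSet) and isinstance(impostor, ScoreSet):
        if genuine.metric != impostor.metric:
            raise ValueError(
                f"metric mismatch: {genuine.metric!r} vs {impostor.metric!r}"
            )
    rows = [
        {
            "threshold": t,
            "fmr": match_rate(impostor, t),
            "fnmr": 1.0 - match_rate(genuine, t),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows), eer(genuine, impostor)


@dataclass(frozen=True)
class LeakageExperimentConfig:
    """Configuration of one leakage experiment.

    Defaults follow the reference protocol: n = 1e5 proposals for t^n, the
    schedule n_j = 1000 j (j = 1..100) for r^n, k = 10 bags, thresholds 0.4
    and 0.431 applied to both metrics.  Scale down ``n_steps``, ``schedule``
    and ``k`` for quick runs.
    """

    schemes: tuple[str, ...] = ("block", "r_dispersion", "z_dispersion")
    sizes: tuple[int, ...] = (4, 8, 16)
    scenario: str = "not_replaced"
    attacks: dict | None = None
    thresholds: tuple[float, ...] = (0.4, 0.431)
    n_steps: int = 100_000
    schedule: SnapshotSchedule = field(
        default_factory=lambda: SnapshotSchedule.linear(1000, 100)
    )
    k: int = 10
    params: IsingParams = field(default_factory=IsingParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("not_replaced", "replaced"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(not 0 < t < 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")

    def attacks_for(self, scheme: str) -> tuple[str, ...]:
        table = self.attacks or DEFAULT_ATTACKS
        return tuple(table[scheme])


@dataclass(frozen=True)
class LeakageResult:
    """Raw per-comparison scores plus IMR tabulation helpers."""

    scores: pd.DataFrame  # subject, scheme, size, attack, leaked_bits, hd, mhd
    thresholds: tuple[float, ...]

    def imr_table(self, threshold: float | None = None) -> pd.DataFrame:
        """IMR per (scheme, attack, size, metric) cell, one row per threshold
        unless a single one is requested."""
        thresholds = self.thresholds if threshold is None else (threshold,)
        rows = []
        grouped = self.scores.groupby(["scheme", "attack", "size"], sort=False)
        for (scheme, attack, size), block in grouped:
            for metric in ("hd", "mhd"):
                vals = block[metric].dropna().to_numpy()
                for t in thresholds:
                    rows.append(
                        {
                            "scheme": scheme,
                            "attack": attack,
                            "size": size,
                            "metric": metric,
                            "threshold": t,
                            "imr": match_rate(vals, t) if len(vals) else np.nan,
                            "n_comparisons": len(vals),
                            "mean_leaked_bits": float(block["leaked_bits"].mean()),
                        }
                    )
        return pd.DataFrame(rows)


def _divide_for(scheme: str, template: Template, m: int, rng):
    if scheme == "block":
        return divide_block(template, default_block_grid(m, template.shape))
    if scheme == "r_dispersion":
        return divide_r_dispersion(template, m, rng)
    if scheme == "z_dispersion":
        return divide_z_dispersion(template, m, rng)
    raise ValueError(f"unknown scheme {scheme!r}")


def _attack_template(
    attack: str,
    scheme: str,
    leaked,
    config: LeakageExperimentConfig,
    stream: np.random.SeedSequence,
) -> Template:
    if attack == "occlusion":
        return occlusion_attack(leaked)
    if attack in ("tn", "rn"):
        source = leaked
        if scheme == "z_dispersion":
            comp_stream, stream = stream.spawn(2)
            source = complementary_partial(leaked, comp_stream).extended
        if attack == "tn":
            return reconstruct_tn(source, config.n_steps, config.params, stream)
        return reconstruct_rn(source, config.schedule, config.params, stream)
    if attack in ("tn_k", "rn_k"):
        mode = attack[:2]
        return bagged_reconstruct(
            leaked,
            config.k,
            mode,
            config.n_steps,
            config.schedule,
            config.params,
            stream,
        )
    raise ValueError(f"unknown attack {attack!r}")


def run_leakage_experiment(
    config: LeakageExperimentConfig, population: list[list[Template]]
) -> LeakageResult:
    """Mount every configured attack on every subject and collect scores.

    In the ``replaced`` scenario each subject needs at least two templates;
    the leaked partial still comes from the first (the compromised
    reference), while comparisons run against the second (the re-enrolled
    capture).
    """
    records = []
    for subject_id, templates in enumerate(population):
        reference = templates[0]
        if config.scenario == "replaced":
            if len(templates) < 2:
                raise ValueError(
                    "replaced scenario needs >= 2 templates per subject"
                )
            target = templates[1]
        else:
            target = reference
        for si, scheme in enumerate(config.schemes):
            for mi, m in enumerate(config.sizes):
                root = np.random.SeedSequence(
                    entropy=config.rng_seed, spawn_key=(subject_id, si, mi)
                )
                div_stream, pick_stream, attack_root = root.spawn(3)
                partials = _divide_for(scheme, reference, m, div_stream)
                pick = np.random.default_rng(pick_stream)
                leaked = partials[int(pick.integers(len(partials)))]
                for ai, attack in enumerate(config.attacks_for(scheme)):
                    stream = np.random.SeedSequence(
                        entropy=config.rng_seed,
                        spawn_key=(subject_id, si, mi, ai),
                    )
                    probe = _attack_template(attack, scheme, leaked, config, stream)
                    try:
                        hd = hamming_distance(probe, target).value
                    except UndefinedScoreError:
                        hd = np.nan
                    mhd = modified_hamming_distance(probe, target).value
                    records.append(
                        {
                            "subject": subject_id,
                            "scheme": scheme,
                            "size": m,
                            "attack": attack,
                            "leaked_bits": len(leaked),
                            "hd": hd,
                            "mhd": mhd,
                        }
                    )
    return LeakageResult(pd.DataFrame(records), tuple(config.thresholds))
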