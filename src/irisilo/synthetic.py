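"""Synthetic template populations for the attack experiments.

No external dataset is required: subject patterns are drawn from the
package's own seeded Ising sampler, which is also the generative story behind
the model — random embryonic initial conditions (the seeds) evolved by local
interaction dynamics.  Sampling the sampler gives binary patterns with the
two statistical features the experiments rely on: roughly half the bits are
0, and the 0s and 1s cluster spatially, so a reconstruction attack has
genuine structure to exploit.  Same-subject recaptures are emulated by
independent per-bit flips, placing genuine scores near the flip rate (default
0.2) and impostor scores near 0.5, i.e. well on either side of the 0.4
operating threshold.  Occlusion, when requested, is a contiguous band plus
speckle.

Everything is a pure function of (config, ids, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ising import IsingParams, SeedMap, metropolis_run
from .templates import Template, from_spin

__all__ = [
    "PopulationConfig",
    "gen_subject_template",
    "gen_genuine_variant",
    "gen_occlusion_mask",
    "generate_population",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Knobs of the synthetic population.

    ``seed_fraction`` is the share of lattice sites frozen as random seeds
    when growing a subject pattern; ``pattern_steps`` the Metropolis proposal
    count (default 20 proposals per site).  ``genuine_flip_rate`` is the
    per-bit recapture noise.
    """

    n_subjects: int = 50
    templates_per_subject: int = 2
    shape: tuple[int, int] = (8, 128)
    params: IsingParams = field(default_factory=IsingParams)
    seed_fraction: float = 1 / 6
    pattern_steps: int | None = None
    genuine_flip_rate: float = 0.2
    occlusion_fraction: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.genuine_flip_rate <= 0.5:
            raise ValueError("genuine_flip_rate must be in [0, 0.5]")
        if not 0.0 <= self.occlusion_fraction < 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1)")
        if self.templates_per_subject < 1:
            raise ValueError("templates_per_subject must be >= 1")

    @property
    def steps(self) -> int:
        return (
            self.pattern_steps
            if self.pattern_steps is not None
            else 20 * self.shape[0] * self.shape[1]
        )


def _subject_stream(config: PopulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=key)
    )


def gen_subject_template(config: PopulationConfig, subject_id: int) -> Template:
    """Grow one subject's base pattern from random seeds via the Ising chain."""
    rng = _subject_stream(config, 0, subject_id)
    q1, q2 = config.shape
    n = q1 * q2
    n_seed = max(1, round(config.seed_fraction * n))
    linear = rng.choice(n, size=n_seed, replace=False)
    positions = np.column_stack([linear // q2, linear % q2])
    spins = rng.integers(0, 2, size=n_seed, dtype=np.int8) * 2 - 1
    seed_map = SeedMap(config.shape, positions, spins)
    (snap,) = metropolis_run(seed_map, config.params, config.steps, None, rng)
    mask = None
    if config.occlusion_fraction > 0:
        mask = gen_occlusion_mask(config.shape, config.occlusion_fraction, rng)
    return from_spin(snap, mask)


def gen_genuine_variant(base: Template, flip_rate: float, rng_seed=None) -> Template:
    """Same-subject recapture: each phase bit flips independently at
    ``flip_rate``; the mask is carried over unchanged."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    flips = (rng.random(base.shape) < flip_rate).astype(np.uint8)
    return Template(base.phase ^ flips, base.mask)


def gen_occlusion_mask(
    shape: tuple[int, int], fraction: float, rng_seed=None
) -> np.ndarray:
    """Occlusion mask with expected invalid share ~= ``fraction``.

    Half the budget is a contiguous band (random rows times a circular column
    arc, the eyelid analog), the rest i.i.d. speckle on the remaining sites.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    q1, q2 = shape
    mask = np.ones(shape, dtype=np.uint8)
    if fraction == 0.0:
        return mask
    rng = np.random.default_rng(rng_seed)
    n = q1 * q2
    band_rows = int(rng.integers(1, q1 + 1))
    width = int(np.clip(round(fraction * n / (2 * band_rows)), 1, q2))
    start = int(rng.integers(q2))
    cols = (start + np.arange(width)) % q2
    mask[:band_rows, cols] = 0
    band_area = band_rows * width
    rest = n - band_area
    p = max(0.0, (fraction * n - band_area) / rest) if rest else 0.0
    speckle = rng.random(shape) < p
    mask[(mask == 1) & speckle] = 0
    return mask


def generate_population(config: PopulationConfig) -> list[list[Template]]:
    """All subjects' templates: element [i][0] is subject i's base pattern,
    the rest are genuine recaptures of it."""
    population = []
    for sid in range(config.n_subjects):
        base = gen_subject_template(config, sid)
        templates = [base]
        for v in range(1, config.templates_per_subject):
            rng = _subject_stream(config, 1, sid, v)
            t = gen_genuine_variant(base, config.genuine_flip_rate, rng)
            if config.occlusion_fraction > 0:
                t = Template(
                    t.phase, gen_occlusion_mask(config.shape, config.occlusion_fraction, rng)
                )
            templates.append(t)
        population.append(templates)
    return population
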