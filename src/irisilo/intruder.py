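"""Reconstruction attacks from a leaked partial template.

Given a leaked partial ``s`` an attacker can mount:

* the *occlusion attack*: submit the leaked bits as a probe whose mask
  invalidates every non-leaked position, so a plain Hamming comparison sees
  only bits the attacker knows to be correct;
* the *t^n attack*: freeze the leaked bits as Ising seeds and take the
  Metropolis chain's state after n proposals as a full probe;
* the *r^n attack*: majority-vote, position by position, over snapshots of
  the chain at proposal counts n_1 < ... < n_L (ties go to +1);
* *bagged* variants t^{n,k} / r^{n,k}: repeat the reconstruction from k
  independently drawn complementary partials and majority-vote the results.

A complementary partial c(s) matters for Z-dispersion leaks, whose bits are
all 0 or all 1: s is extended on a random disjoint position set I' of equal
size with values chosen so 0-bits make up 50% of the extended support,
restoring the bit balance real templates have.

Reconstructed templates carry an all-valid mask — they pose as complete
probes — while the occlusion-attack template carries the leak-shaped mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ising import IsingParams, SeedMap, metropolis_run
from .templates import PartialTemplate, SpinView, Template, from_spin, to_spin

__all__ = [
    "SnapshotSchedule",
    "ComplementaryPartial",
    "occlusion_attack",
    "reconstruct_tn",
    "reconstruct_rn",
    "snapshot_majority",
    "complementary_partial",
    "bagged_reconstruct",
]

DEFAULT_N = 100_000  # proposal count behind t^n


@dataclass(frozen=True)
class SnapshotSchedule:
    """Strictly increasing proposal counts n = (n_1, ..., n_L) for r^n."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if not counts:
            raise ValueError("snapshot schedule must be nonempty")
        if counts[0] < 0 or any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("snapshot counts must satisfy 0 <= n_1 < ... < n_L")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def linear(cls, step: int = 1000, length: int = 100) -> "SnapshotSchedule":
        """The default schedule n_j = step * j, j = 1..length."""
        return cls(tuple(step * j for j in range(1, length + 1)))

    @property
    def last(self) -> int:
        return self.counts[-1]

    def __len__(self) -> int:
        return len(self.counts)


def occlusion_attack(leaked: PartialTemplate) -> Template:
    """Full-size probe whose mask validates exactly the leaked bits."""
    shape = leaked.origin_shape
    phase = np.zeros(shape, dtype=np.uint8)
    mask = np.zeros(shape, dtype=np.uint8)
    r, c = leaked.positions[:, 0], leaked.positions[:, 1]
    phase[r, c] = leaked.values
    mask[r, c] = leaked.mask_values
    return Template(phase, mask)


def reconstruct_tn(
    s: PartialTemplate,
    n: int = DEFAULT_N,
    params: IsingParams = IsingParams(),
    rng_seed=None,
    init: SpinView | None = None,
) -> Template:
    """The t^n intruder template: a single Metropolis endpoint at n proposals."""
    seed_map = SeedMap.from_partial(s)
    (snap,) = metropolis_run(seed_map, params, n, [n], rng_seed, init)
    return from_spin(snap)


def reconstruct_rn(
    s: PartialTemplate,
    schedule: SnapshotSchedule | None = None,
    params: IsingParams = IsingParams(),
    rng_seed=None,
    init: SpinView | None = None,
) -> Template:
    """The r^n intruder template: per-position majority over trajectory
    snapshots at the scheduled proposal counts."""
    schedule = schedule or SnapshotSchedule.linear()
    seed_map = SeedMap.from_partial(s)
    snaps = metropolis_run(
        seed_map, params, schedule.last, schedule.counts, rng_seed, init
    )
    return from_spin(snapshot_majority(snaps))


def snapshot_majority(snapshots: Sequence[SpinView]) -> SpinView:
    """Per-position sign of the snapshot sum; a tied position (sum 0) is +1."""
    if not snapshots:
        raise ValueError("majority vote needs at least one snapshot")
    shape = snapshots[0].shape
    total = np.zeros(shape, dtype=np.int64)
    for s in snapshots:
        if s.shape != shape:
            raise ValueError("snapshots must share one shape")
        total += s.values
    return SpinView(np.where(total >= 0, 1, -1).astype(np.int8))


@dataclass(frozen=True)
class ComplementaryPartial:
    """A leaked partial s on I extended to c(s) on I union I'."""

    base: PartialTemplate
    extension_positions: np.ndarray
    extended: PartialTemplate


def complementary_partial(s: PartialTemplate, rng_seed=None) -> ComplementaryPartial:
    """Extend s on a random disjoint I' with |I'| = |I| so that 0-bits make up
    50% (rounded up) of the extended support.

    The extension bit values are placed uniformly at random among the I'
    positions; extension mask bits are valid.  Reproducible from ``rng_seed``.
    """
    q1, q2 = s.origin_shape
    n_sites = q1 * q2
    n_i = len(s)
    if n_i == 0:
        raise ValueError("cannot complement an empty partial template")
    if 2 * n_i > n_sites:
        raise ValueError(
            f"no room for a disjoint extension: 2 * {n_i} > {n_sites} lattice sites"
        )
    rng = np.random.default_rng(rng_seed)
    taken = np.zeros(n_sites, dtype=bool)
    taken[s.positions[:, 0] * q2 + s.positions[:, 1]] = True
    candidates = np.flatnonzero(~taken)
    ext_linear = rng.choice(candidates, size=n_i, replace=False)
    ext_positions = np.column_stack([ext_linear // q2, ext_linear % q2])

    target_zeros = math.ceil(2 * n_i / 2)
    n0 = int((s.values == 0).sum())
    ext_zeros = target_zeros - n0
    if not 0 <= ext_zeros <= n_i:
        raise ValueError(
            f"cannot reach {target_zeros} zeros over the extended support: "
            f"base has {n0} zeros, extension holds {n_i} bits"
        )
    ext_values = np.zeros(n_i, dtype=np.uint8)
    ext_values[ext_zeros:] = 1
    ext_values = rng.permutation(ext_values)

    extended = PartialTemplate(
        s.origin_shape,
        np.concatenate([s.positions, ext_positions]),
        np.concatenate([s.values, ext_values]),
        np.concatenate([s.mask_values, np.ones(n_i, dtype=np.uint8)]),
    )
    return ComplementaryPartial(s, ext_positions, extended)


def _bag_streams(rng_seed, k: int) -> list[np.random.SeedSequence]:
    """One independent, replayable sub-stream per bag."""
    if isinstance(rng_seed, np.random.SeedSequence):
        root = rng_seed
    else:
        root = np.random.SeedSequence(rng_seed)
    return root.spawn(k)


def bagged_reconstruct(
    s: PartialTemplate,
    k: int = 10,
    mode: str = "rn",
    n: int = DEFAULT_N,
    schedule: SnapshotSchedule | None = None,
    params: IsingParams = IsingParams(),
    rng_seed=None,
) -> Template:
    """t^{n,k} / r^{n,k}: majority vote over k reconstructions, each from its
    own complementary partial c_j(s).  Ties go to +1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("tn", "rn"):
        raise ValueError(f"mode must be 'tn' or 'rn', got {mode!r}")
    members = []
    for stream in _bag_streams(rng_seed, k):
        comp_stream, run_stream = stream.spawn(2)
        c = complementary_partial(s, comp_stream)
        if mode == "tn":
            t = reconstruct_tn(c.extended, n, params, run_stream)
        else:
            t = reconstruct_rn(c.extended, schedule, params, run_stream)
        members.append(to_spin(t))
    return from_spin(snapshot_majority(members))
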