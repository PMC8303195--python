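"""Seeded Ising model on the template lattice and its Metropolis sampler.

The model places a Gibbs distribution over spin lattices x in {-1, +1}^(q1 x q2)
conditioned on a set of frozen "seed" spins s on positions I:

    P(x) = exp(Jv sum_{i ~v j} x_i x_j + Jh sum_{i ~h j} x_i x_j) / Z,
    x restricted to T(s) = {x : x_k = s(k) for k in I}.

Vertical adjacency is open (q1 - 1 edges per column); horizontal adjacency is
circular within each row (q2 edges per row), matching the row-circular
geometry of unwrapped iris codes.  Up to normalization the probability is
pi(x) = exp(-2 Jv d_v - 2 Jh d_h) with d_v, d_h the disagreeing edge counts,
which is what the sampler and the exact-enumeration oracle both use.

The sampler is single-site Metropolis: one iteration proposes flipping one
uniformly drawn non-seed site and accepts with probability min(1, pi(x')/pi(x)).
The flip ratio only needs the proposal site's neighborhood:
exp(2 Jv (d_k^v - a_k^v) + 2 Jh (d_k^h - a_k^h)) with d/a the disagreeing and
agreeing edge counts at the site.  Draw order is fixed for reproducibility:
the free-site initialization (when no initial lattice is supplied) is drawn
first, then proposal indices and acceptance uniforms are drawn in blocks from
the same generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .templates import PartialTemplate, SpinView, TemplateError

__all__ = [
    "IsingParams",
    "SeedMap",
    "SeedViolationError",
    "edge_disagreements",
    "unnormalized_prob",
    "flip_site",
    "acceptance_ratio",
    "metropolis_run",
    "enumerate_gibbs",
    "GibbsTable",
]


class SeedViolationError(ValueError):
    """A seed site was used where a free site is required."""


@dataclass(frozen=True)
class IsingParams:
    """Coupling constants: ``jv`` for vertical, ``jh`` for horizontal edges."""

    jv: float = 0.2
    jh: float = 0.3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.jv) and math.isfinite(self.jh)):
            raise ValueError("coupling constants must be finite")


@dataclass(frozen=True, eq=False)
class SeedMap:
    """Frozen spins s: I -> {-1, +1} on a q1 x q2 lattice.

    ``positions`` may be empty (plain Ising model) or cover the whole lattice
    (fully frozen; sampling then returns the seed template unchanged).
    """

    shape: tuple[int, int]
    positions: np.ndarray
    spins: np.ndarray

    def __post_init__(self) -> None:
        q1, q2 = (int(v) for v in self.shape)
        if q1 < 1 or q2 < 3:
            raise TemplateError(f"lattice must be at least 1 x 3, got {q1} x {q2}")
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise TemplateError("positions must be an (n, 2) array")
        if pos.size:
            if pos.min() < 0 or pos[:, 0].max() >= q1 or pos[:, 1].max() >= q2:
                raise TemplateError("seed positions outside the lattice")
            if len(np.unique(pos, axis=0)) != len(pos):
                raise TemplateError("seed positions must be distinct")
        spins = np.asarray(self.spins)
        if spins.shape != (len(pos),):
            raise TemplateError("one spin per seed position required")
        if spins.size and not np.isin(spins, (-1, 1)).all():
            raise TemplateError("seed spins must be -1 or +1")
        pos.setflags(write=False)
        spins = spins.astype(np.int8)
        spins.setflags(write=False)
        object.__setattr__(self, "shape", (q1, q2))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "spins", spins)

    @classmethod
    def from_partial(cls, partial: PartialTemplate) -> "SeedMap":
        """Treat a (leaked) partial template's bit values as seed spins."""
        return cls(partial.origin_shape, partial.positions, partial.spins)

    @property
    def n_free(self) -> int:
        return self.shape[0] * self.shape[1] - len(self.positions)

    def seed_linear(self) -> np.ndarray:
        """Seed positions as 0-based row-major linear indices."""
        return self.positions[:, 0] * self.shape[1] + self.positions[:, 1]

    def free_linear(self) -> np.ndarray:
        """Non-seed positions as 0-based row-major linear indices."""
        n = self.shape[0] * self.shape[1]
        free = np.ones(n, dtype=bool)
        free[self.seed_linear()] = False
        return np.flatnonzero(free)

    def contains(self, x: SpinView) -> bool:
        """Whether x lies in T(s)."""
        if x.shape != self.shape:
            return False
        if not len(self.positions):
            return True
        return bool(
            (x.values[self.positions[:, 0], self.positions[:, 1]] == self.spins).all()
        )


def edge_disagreements(x: SpinView) -> tuple[int, int]:
    """(vertical, horizontal) disagreeing edge counts; rows are circular."""
    v = x.values
    dv = int((v[:-1, :] != v[1:, :]).sum())
    dh = int((v != np.roll(v, -1, axis=1)).sum())
    return dv, dh


def unnormalized_prob(x: SpinView, params: IsingParams) -> float:
    """pi(x) = exp(-2 Jv d_v - 2 Jh d_h)."""
    dv, dh = edge_disagreements(x)
    return math.exp(-2.0 * params.jv * dv - 2.0 * params.jh * dh)


def flip_site(x: SpinView, site: tuple[int, int]) -> SpinView:
    """x with the spin at ``site`` negated."""
    v = x.values.copy()
    v[site] = -v[site]
    return SpinView(v)


def acceptance_ratio(
    x: SpinView,
    site: tuple[int, int],
    params: IsingParams,
    seed_map: SeedMap | None = None,
) -> float:
    """pi(x') / pi(x) for x' = x with the spin at ``site`` flipped.

    The Metropolis acceptance probability is min(1, ratio).  If a seed map is
    given, flipping a seed site raises :class:`SeedViolationError`.
    """
    r, c = site
    q1, q2 = x.shape
    if not (0 <= r < q1 and 0 <= c < q2):
        raise TemplateError(f"site {site} outside the {q1} x {q2} lattice")
    if seed_map is not None and len(seed_map.positions):
        if ((seed_map.positions[:, 0] == r) & (seed_map.positions[:, 1] == c)).any():
            raise SeedViolationError(f"site {site} is a frozen seed")
    v = x.values
    s = int(v[r, c])
    sv = 0
    if r > 0:
        sv += int(v[r - 1, c])
    if r < q1 - 1:
        sv += int(v[r + 1, c])
    sh = int(v[r, (c - 1) % q2]) + int(v[r, (c + 1) % q2])
    return math.exp(-2.0 * s * (params.jv * sv + params.jh * sh))


def _validate_snapshots(snapshots: Sequence[int], n_steps: int) -> list[int]:
    counts = [int(c) for c in snapshots]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError("snapshot schedule must be strictly increasing")
    if counts and (counts[0] < 0 or counts[-1] > n_steps):
        raise ValueError(
            f"snapshots must lie in 0..{n_steps}, got {counts[0]}..{counts[-1]}"
        )
    return counts


def metropolis_run(
    seed_map: SeedMap,
    params: IsingParams,
    n_steps: int,
    snapshots: Sequence[int] | None = None,
    rng_seed=None,
    init: SpinView | None = None,
) -> list[SpinView]:
    """Run the seeded Metropolis chain and return the requested snapshots.

    One iteration is one proposal (accepted or not).  Snapshot indices are
    proposal counts; index 0 is the initial template.  When ``init`` is not
    given, free spins start i.i.d. uniform on {-1, +1} from the run's RNG;
    a supplied ``init`` must lie in T(s).  The returned list follows the
    snapshot order; with ``snapshots=None`` a single snapshot at ``n_steps``
    is returned.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    counts = _validate_snapshots(
        [n_steps] if snapshots is None else snapshots, n_steps
    )
    rng = np.random.default_rng(rng_seed)
    q1, q2 = seed_map.shape
    n_sites = q1 * q2
    free = seed_map.free_linear()

    lattice = np.zeros(n_sites, dtype=np.int8)
    lattice[seed_map.seed_linear()] = seed_map.spins
    if init is not None:
        if not seed_map.contains(init):
            raise TemplateError("initial template does not honor the seed map")
        lattice = init.values.ravel().astype(np.int8).copy()
    elif len(free):
        lattice[free] = rng.integers(0, 2, size=len(free), dtype=np.int8) * 2 - 1

    def snap() -> SpinView:
        return SpinView(np.array(x, dtype=np.int8).reshape(q1, q2))

    x = lattice.tolist()
    out: list[SpinView] = []
    ptr = 0
    if ptr < len(counts) and counts[ptr] == 0:
        out.append(snap())
        ptr += 1
    if not len(free):  # fully frozen lattice: no proposal can do anything
        while ptr < len(counts):
            out.append(snap())
            ptr += 1
        return out

    # Neighbor tables per free site (vertical open, horizontal circular).
    free_list = free.tolist()
    vnb: list[list[int]] = []
    hnb: list[list[int]] = []
    for k in free_list:
        r, c = divmod(k, q2)
        vs = []
        if r > 0:
            vs.append(k - q2)
        if r < q1 - 1:
            vs.append(k + q2)
        vnb.append(vs)
        hnb.append([r * q2 + (c - 1) % q2, r * q2 + (c + 1) % q2])

    jv, jh = float(params.jv), float(params.jh)
    exp = math.exp
    n_free = len(free_list)
    chunk = 1 << 16
    done = 0
    n_counts = len(counts)
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        fidx = rng.integers(0, n_free, size=todo).tolist()
        us = rng.random(todo).tolist()
        for i in range(todo):
            fi = fidx[i]
            k = free_list[fi]
            s = x[k]
            e = 0
            for j in vnb[fi]:
                e += x[j]
            field = jv * e
            e = 0
            for j in hnb[fi]:
                e += x[j]
            field += jh * e
            delta = -2.0 * s * field
            if delta >= 0.0 or us[i] < exp(delta):
                x[k] = -s
            if ptr < n_counts and counts[ptr] == done + i + 1:
                out.append(snap())
                ptr += 1
        done += todo
    return out


class GibbsTable:
    """Exact distribution over T(s), indexed by lattice content."""

    def __init__(self, states: list[SpinView], probs: np.ndarray) -> None:
        self.states = states
        self.probs = probs
        self._index = {s.values.tobytes(): i for i, s in enumerate(states)}

    def prob(self, x: SpinView) -> float:
        """Exact probability of x; 0.0 if x is outside T(s)."""
        i = self._index.get(x.values.tobytes())
        return 0.0 if i is None else float(self.probs[i])

    def tv_distance(self, samples: Sequence[SpinView]) -> float:
        """Total-variation distance between the empirical law of ``samples``
        and the exact distribution."""
        counts = np.zeros(len(self.states))
        outside = 0
        for s in samples:
            i = self._index.get(s.values.tobytes())
            if i is None:
                outside += 1
            else:
                counts[i] += 1
        emp = counts / len(samples)
        return 0.5 * (np.abs(emp - self.probs).sum() + outside / len(samples))


def enumerate_gibbs(
    seed_map: SeedMap, params: IsingParams, max_free: int = 20
) -> GibbsTable:
    """Exact enumeration of P(x) over T(s); the sampler's independent oracle.

    Feasible only for small free sets; refuses beyond ``max_free`` free bits.
    """
    free = seed_map.free_linear()
    if len(free) > max_free:
        raise ValueError(
            f"{len(free)} free bits exceed the enumeration limit of {max_free}"
        )
    q1, q2 = seed_map.shape
    base = np.zeros(q1 * q2, dtype=np.int8)
    base[seed_map.seed_linear()] = seed_map.spins
    states: list[SpinView] = []
    weights = []
    for combo in product((-1, 1), repeat=len(free)):
        v = base.copy()
        v[free] = combo
        state = SpinView(v.reshape(q1, q2))
        states.append(state)
        weights.append(unnormalized_prob(state, params))
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    return GibbsTable(states, probs)
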