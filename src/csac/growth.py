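"""Chain growth by geometric sequential importance sampling.

Chains are grown one persistence unit at a time.  At each step the ``k``
candidate directions (a Fibonacci-sphere set, randomly rotated once per
chain) are screened for feasibility: a direction is feasible when the unit
boundary bead *and* every interpolated bead on the rigid segment neither
overlaps an existing bead nor leaves the confinement sphere.  One feasible
direction is drawn uniformly and the chain weight accumulates the factor
``m_t / k`` (``m_t`` = number of feasible directions), the normalized
Rosenbluth weight correcting the growth bias so that weighted averages
target the uniform distribution over all realizable confined chains.

Dead ends (``m_t = 0``) are discarded and restarted from a fresh sub-seed;
the number of abandoned attempts is reported as *attrition*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from . import _kernels
from .model import (ConfigurationError, Conformation, ModelParameters,
                    WeightedEnsemble, DEFAULT_PARAMS, DISTANCE_TOL,
                    bead_count)

__all__ = [
    "CandidateSet",
    "GrowthRecord",
    "GrowthError",
    "make_candidate_set",
    "fibonacci_sphere",
    "feasible_moves",
    "grow_chain",
    "grow_ensemble",
]

FREE = None  # sentinel for unconfined growth


class GrowthError(RuntimeError):
    """Chain generation failed (e.g. attrition above the configured ceiling)."""


@dataclass(frozen=True)
class CandidateSet:
    """The k discrete candidate directions for the next persistence unit."""

    directions: np.ndarray  # (k, 3) unit vectors
    generation_mode: str = "rotated_per_chain"  # or "fixed_global"

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 2:
            raise ValueError("directions must be a (k>=2, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("candidate directions must be unit vectors")
        object.__setattr__(self, "directions", np.ascontiguousarray(d))
        if self.generation_mode not in ("fixed_global", "rotated_per_chain"):
            raise ValueError(f"unknown generation_mode {self.generation_mode!r}")

    @property
    def k(self) -> int:
        return self.directions.shape[0]


def fibonacci_sphere(k: int) -> np.ndarray:
    """k near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(k, dtype=np.float64) + 0.5
    z = 1.0 - 2.0 * i / k
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_candidate_set(k: int, seed: Optional[int] = None,
                       mode: str = "rotated_per_chain") -> CandidateSet:
    """Build the k-state direction set.

    With a seed, the base Fibonacci set is given one fixed random rotation
    (useful for ``fixed_global`` mode); the per-chain re-rotation that
    restores full rotational isotropy happens inside the grower when
    ``mode="rotated_per_chain"``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    dirs = fibonacci_sphere(k)
    if seed is not None:
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=np.random.default_rng(seed))
        dirs = dirs @ rot.as_matrix().T
    return CandidateSet(directions=dirs, generation_mode=mode)


@dataclass
class GrowthRecord:
    """Per-step bookkeeping of one growth attempt."""

    m_counts: np.ndarray  # available candidates at each step
    final_status: str  # "completed" | "dead_end"
    steps_completed: int


def _r_allow_nm(d_um: Optional[float], params: ModelParameters) -> float:
    """Max allowed bead-centre radius; inf for unconfined growth."""
    if d_um is None or (isinstance(d_um, float) and math.isinf(d_um)):
        return math.inf
    d_nm = float(d_um) * 1000.0
    if d_nm <= params.bead_diameter_nm:
        raise ConfigurationError("confinement diameter must exceed the bead diameter")
    return d_nm / 2.0 - params.bead_diameter_nm / 2.0


def feasible_moves(partial: Union[Conformation, np.ndarray],
                   candidates: CandidateSet,
                   D_um: Optional[float],
                   params: ModelParameters = DEFAULT_PARAMS) -> np.ndarray:
    """Indices of candidate directions on which the next unit can be placed.

    ``partial`` is a valid partial chain (a Conformation or a bead-coordinate
    array); the move is evaluated from its last bead.
    """
    coords = partial.coordinates if isinstance(partial, Conformation) else np.asarray(partial, float)
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    mask = _kernels.feasible_mask_kernel(
        coords, coords[-1], candidates.directions, _r_allow_nm(D_um, params),
        params.bead_diameter_nm, params.beads_per_unit, DISTANCE_TOL)
    return np.flatnonzero(mask)


def grow_chain(n_units: int,
               d_um: Optional[float],
               params: ModelParameters = DEFAULT_PARAMS,
               seed: int = 0,
               candidates: Optional[CandidateSet] = None,
               ) -> Tuple[Optional[Conformation], GrowthRecord]:
    """Grow a single chain; returns ``(conformation_or_None, record)``.

    A dead end (no feasible direction at some step) is a normal outcome:
    the conformation is ``None`` and the record reports where growth stopped.
    Identical arguments always produce identical output.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    if candidates is None:
        candidates = make_candidate_set(params.k_states)
    rotate = candidates.generation_mode == "rotated_per_chain"
    status, coords, log_w, steps, m_counts = _kernels.grow_chain_kernel(
        n_units, params.beads_per_unit, params.bead_diameter_nm,
        candidates.directions, _r_allow_nm(d_um, params),
        int(seed) % (2 ** 32), rotate, DISTANCE_TOL)
    if status == _kernels.DEAD_END:
        return None, GrowthRecord(m_counts, "dead_end", steps)
    conf = Conformation(coordinates=coords, n_units=n_units, log_weight=log_w,
                        confinement_diameter_um=None if d_um is None or math.isinf(d_um) else float(d_um),
                        seed=int(seed), params=params)
    return conf, GrowthRecord(m_counts, "completed", steps)


def _subseed(master: int, chain: int, attempt: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(chain, attempt))
    return int(ss.generate_state(1)[0])


def _systematic_resample(weights: np.ndarray, u: float) -> np.ndarray:
    """Systematic resampling: ancestor indices for normalized weights."""
    n = len(weights)
    positions = (u + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


def grow_ensemble(n_chains: int,
                  n_units: int,
                  d_um: Optional[float],
                  params: ModelParameters = DEFAULT_PARAMS,
                  seed: int = 0,
                  candidates: Optional[CandidateSet] = None,
                  max_attrition: float = 0.999,
                  resample_interval: Optional[int] = 5,
                  resample_threshold: float = 0.5,
                  island_size: Optional[int] = None,
                  ) -> WeightedEnsemble:
    """Grow exactly ``n_chains`` chains under one (N, D) condition.

    By default the whole population grows in lockstep with systematic
    resampling (sequential Monte Carlo): every ``resample_interval``
    units, when the effective sample size of the running Rosenbluth
    weights drops below ``resample_threshold * n_chains`` — or any chain
    has hit a dead end — chains are resampled in proportion to their
    weights and the weights reset to their mean.  This population control
    is what keeps severely confined long-chain ensembles usable: plain
    independent growth leaves a single chain carrying essentially all the
    weight (ESS ~ 1) at the nuclear-density condition.  Resampling makes
    chains share ancestry, so they are exchangeable but not independent;
    protocol-level uncertainties are best measured from independent
    replicate runs (different master seeds).  Dead ends are pruned by the
    resampling step and counted as attrition.

    ``island_size`` splits the population into independent sub-populations
    recorded as ``family_ids`` (the independence unit for bootstrap
    resampling); note that small islands trade the global estimator's
    small self-normalization bias for per-island bias, so the default is
    a single population.  ``resample_interval=None`` selects plain
    independent growth with restart-on-dead-end (useful for small chains
    and for validating the weighting itself).  Everything derives
    deterministically from the master seed.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if candidates is None:
        candidates = make_candidate_set(params.k_states)
    d_out = None if d_um is None or (isinstance(d_um, float) and math.isinf(d_um)) else float(d_um)

    if resample_interval is None:
        return _grow_ensemble_plain(n_chains, n_units, d_um, d_out, params,
                                    seed, candidates, max_attrition)

    rotate = candidates.generation_mode == "rotated_per_chain"
    r_allow = _r_allow_nm(d_um, params)
    n_beads = bead_count(n_units, params)

    if island_size is None:
        island_size = n_chains
    confs = []
    fam_out = []
    attrition_total = 0
    n_islands = (n_chains + island_size - 1) // island_size
    for isl in range(n_islands):
        size = min(island_size, n_chains - isl * island_size)
        for attempt in range(50):
            try:
                island_confs, attr = _grow_island(
                    size, n_units, n_beads, r_allow, d_out, params,
                    candidates, rotate, seed, isl, attempt,
                    resample_interval, resample_threshold, max_attrition)
                break
            except GrowthError:
                attrition_total += size
                if attempt == 49:
                    raise
        attrition_total += attr
        confs.extend(island_confs)
        fam_out.extend([isl] * size)
    return WeightedEnsemble(conformations=confs, n_units=n_units,
                            confinement_diameter_um=d_out, params=params,
                            attrition_count=attrition_total,
                            master_seed=int(seed),
                            family_ids=np.array(fam_out)
                            if n_islands > 1 else None)


def _grow_island(n_chains, n_units, n_beads, r_allow, d_out, params,
                 candidates, rotate, seed, island, attempt,
                 resample_interval, resample_threshold, max_attrition):
    """One independent SMC population; raises GrowthError on extinction."""
    coords = np.zeros((n_chains, n_beads, 3))
    n_placed = np.zeros(n_chains, dtype=np.int64)
    log_w = np.zeros(n_chains)
    attrition = 0
    tag = (island << 8) | attempt
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(0xE5A, tag)))

    units_done = 0
    ckpt = 0
    while units_done < n_units - 1:
        step = min(resample_interval, n_units - 1 - units_done)
        dead = np.zeros(n_chains, dtype=bool)
        for i in range(n_chains):
            if not np.isfinite(log_w[i]):
                continue
            status, np_i, dlw, _done = _kernels.extend_chain_kernel(
                coords[i], int(n_placed[i]), step, params.beads_per_unit,
                params.bead_diameter_nm, candidates.directions, r_allow,
                _subseed(seed, (tag << 16) | i, ckpt), rotate, DISTANCE_TOL)
            n_placed[i] = np_i
            log_w[i] += dlw
            if status == _kernels.DEAD_END:
                dead[i] = True
                log_w[i] = -math.inf
        units_done += step
        ckpt += 1
        attrition += int(dead.sum())
        alive = np.isfinite(log_w)
        if not alive.any():
            raise GrowthError(
                f"island population extinct (N={n_units}, D={d_out} um)")
        if attrition / (n_chains * ckpt) > max_attrition:
            raise GrowthError(
                f"attrition rate exceeds ceiling {max_attrition} "
                f"(N={n_units}, D={d_out} um)")
        lw = log_w[alive]
        m = lw.max()
        w = np.exp(lw - m)
        ess = w.sum() ** 2 / (w ** 2).sum()
        final = units_done >= n_units - 1
        if not final and (dead.any() or ess < resample_threshold * n_chains):
            full_w = np.zeros(n_chains)
            full_w[alive] = w
            full_w /= full_w.sum()
            idx = _systematic_resample(full_w, rng.random())
            coords = coords[idx].copy()
            n_placed = n_placed[idx].copy()
            # selection probability already encodes the weights: reset to
            # the mean so the island keeps its absolute Rosenbluth scale
            mean_lw = m + math.log(np.exp(lw - m).mean() * alive.mean()
                                   + 1e-300)
            log_w = np.full(n_chains, mean_lw)
        elif final and dead.any():
            # no weight-proportional resampling after the last unit (it
            # would only duplicate chains); dead chains are replaced by
            # uniform draws among the survivors, carrying their weights
            alive_idx = np.flatnonzero(alive)
            for i in np.flatnonzero(dead):
                j = int(alive_idx[int(rng.integers(len(alive_idx)))])
                coords[i] = coords[j]
                n_placed[i] = n_placed[j]
                log_w[i] = log_w[j]

    return [Conformation(
        coordinates=coords[i], n_units=n_units, log_weight=float(log_w[i]),
        confinement_diameter_um=d_out,
        seed=_subseed(seed, (tag << 16) | i, 0x5EED), params=params)
        for i in range(n_chains)], attrition


def _grow_ensemble_plain(n_chains, n_units, d_um, d_out, params, seed,
                         candidates, max_attrition):
    confs = []
    attrition = 0
    attempts = 0
    for i in range(n_chains):
        attempt = 0
        while True:
            attempts += 1
            conf, _rec = grow_chain(n_units, d_um, params,
                                    seed=_subseed(seed, i, attempt),
                                    candidates=candidates)
            if conf is not None:
                confs.append(conf)
                break
            attrition += 1
            attempt += 1
            if attempts >= 200 and attrition / attempts > max_attrition:
                raise GrowthError(
                    f"attrition rate {attrition/attempts:.4f} exceeds ceiling "
                    f"{max_attrition} after {attempts} attempts "
                    f"(N={n_units}, D={d_um} um)")
    return WeightedEnsemble(conformations=confs, n_units=n_units,
                            confinement_diameter_um=d_out,
                            params=params, attrition_count=attrition,
                            master_seed=int(seed))
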