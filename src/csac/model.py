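"""Physical model of the chromatin fiber and its validity predicates.

The chromatin fiber is coarse-grained as a chain of touching spherical beads
of diameter ``d_f`` (30 nm, ~3 kbp each).  Every ``L_p / d_f`` consecutive
beads form one rigid *persistence unit* of length ``L_p`` (150 nm): the unit
boundary beads are the degrees of freedom of the chain and the beads in
between are interpolated on the straight segment joining them.  A chain of
``N`` persistence units therefore carries

    N' = N + (N - 1) * (L_p/d_f - 1)

beads in total.  Chains may be grown inside a spherical confinement of
diameter ``D`` representing the nuclear sub-volume available to the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ModelParameters",
    "Conformation",
    "WeightedEnsemble",
    "bead_count",
    "confinement_diameter_for",
    "packed_nucleus_diameter",
    "check_self_avoidance",
    "check_confinement",
    "DEFAULT_PARAMS",
]

#: equality tolerance (nm) for bead-distance comparisons
DISTANCE_TOL = 1e-6


class ConfigurationError(ValueError):
    """Inconsistent or physically impossible model parameters."""


class ValidationError(ValueError):
    """A conformation violates a model invariant."""


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the chromatin fiber and its confinement.

    Parameters
    ----------
    bead_diameter_nm
        Fiber (bead) diameter ``d_f``; also the hard-core excluded-volume
        distance between non-bonded beads.
    persistence_length_nm
        Persistence length ``L_p``; must be an integer multiple of the bead
        diameter.
    bp_per_bead
        DNA content of one bead, used only for genomic-distance labeling.
    k_states
        Number of discrete candidate directions evaluated at each growth
        step of the chain-growth sampler.
    confinement_diameter_um
        Default confinement sphere diameter ``D`` in micrometres.
    contact_radius_nm
        Centre-centre distance below which two beads are "in contact".
        Default ``2 * d_f``; exponent estimates are insensitive to this
        prefactor.
    """

    bead_diameter_nm: float = 30.0
    persistence_length_nm: float = 150.0
    bp_per_bead: float = 3000.0
    k_states: int = 100
    confinement_diameter_um: float = 1.5
    contact_radius_nm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("bead_diameter_nm", "persistence_length_nm", "bp_per_bead",
                     "confinement_diameter_um", "contact_radius_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.k_states < 2:
            raise ConfigurationError("k_states must be at least 2")
        ratio = self.persistence_length_nm / self.bead_diameter_nm
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "persistence_length_nm must be an integer multiple of "
                f"bead_diameter_nm (got ratio {ratio!r})"
            )

    @property
    def beads_per_unit(self) -> int:
        """Number of beads per persistence unit, ``L_p / d_f``."""
        return int(round(self.persistence_length_nm / self.bead_diameter_nm))

    @property
    def kbp_per_unit(self) -> float:
        return self.beads_per_unit * self.bp_per_bead / 1e3

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


DEFAULT_PARAMS = ModelParameters()


def bead_count(n_units: int, params: ModelParameters = DEFAULT_PARAMS) -> int:
    """Total number of beads N' in a chain of ``n_units`` persistence units.

    ``N' = N + (N - 1) * (L_p/d_f - 1)``: every unit past the first adds
    ``beads_per_unit`` beads (its interpolated beads plus its boundary bead).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return n_units + (n_units - 1) * (params.beads_per_unit - 1)


def confinement_diameter_for(chain_bp: float, nucleus_diameter_um: float,
                             genome_bp: float) -> float:
    """Confinement diameter giving the chain its genome-proportional share
    of the nuclear volume (equal DNA density in a sub-sphere):

        D = D_nucleus * (chain_bp / genome_bp) ** (1/3)
    """
    if chain_bp <= 0 or nucleus_diameter_um <= 0 or genome_bp <= 0:
        raise ValueError("all arguments must be positive")
    if chain_bp > genome_bp:
        raise ValueError("chain_bp cannot exceed genome_bp")
    return nucleus_diameter_um * (chain_bp / genome_bp) ** (1.0 / 3.0)


def packed_nucleus_diameter(chain_bp: float, genome_bp: float,
                            confinement_diameter_um: float) -> float:
    """Diameter of a nucleus tiled by close-packed sub-spheres of diameter D,
    one per ``chain_bp`` of DNA: ``(genome_bp/chain_bp)^(1/3) * D``.
    With 15 Mb per 1.5 um region and a 6 Gb genome this gives
    400^(1/3) * 1.5 um ~ 11 um, the observed human nuclear diameter.
    """
    n_regions = genome_bp / chain_bp
    if n_regions < 1:
        raise ValueError("genome_bp must be at least chain_bp")
    return n_regions ** (1.0 / 3.0) * confinement_diameter_um


@dataclass
class Conformation:
    """One chain: ordered bead coordinates plus its importance weight.

    ``coordinates`` has shape (N', 3) in nm.  ``log_weight`` is the natural
    log of the sequential-importance-sampling weight; it is stored in log
    form because severely confined long chains underflow a plain float.
    """

    coordinates: np.ndarray
    n_units: int
    log_weight: float
    confinement_diameter_um: Optional[float]  # None => unconfined
    seed: int
    params: ModelParameters = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self) -> None:
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_beads, 3)")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    @property
    def weight(self) -> float:
        return math.exp(self.log_weight)

    @property
    def unit_indices(self) -> np.ndarray:
        """Indices of persistence-unit boundary beads (every beads_per_unit-th)."""
        return np.arange(0, self.n_beads, self.params.beads_per_unit)

    @property
    def unit_coordinates(self) -> np.ndarray:
        return self.coordinates[self.unit_indices]

    @property
    def dna_kbp(self) -> float:
        return self.n_beads * self.params.bp_per_bead / 1e3

    def radius_of_gyration(self) -> float:
        c = self.coordinates - self.coordinates.mean(axis=0)
        return float(np.sqrt((c ** 2).sum(axis=1).mean()))


@dataclass
class WeightedEnsemble:
    """Conformations from one (N, D) condition with weight accessors."""

    conformations: list
    n_units: int
    confinement_diameter_um: Optional[float]
    params: ModelParameters
    attrition_count: int = 0
    master_seed: Optional[int] = None
    #: genealogy labels when grown with population resampling: chains
    #: sharing a root ancestor are statistically dependent, and resampling
    #: procedures (bootstraps) should treat a family as one unit
    family_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.conformations:
            raise ValueError("ensemble must contain at least one conformation")
        for c in self.conformations:
            if c.n_units != self.n_units:
                raise ValidationError("all members must share n_units")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self):
        return iter(self.conformations)

    @property
    def condition(self):
        return (self.n_units, self.confinement_diameter_um)

    @property
    def log_weights(self) -> np.ndarray:
        return np.array([c.log_weight for c in self.conformations])

    @property
    def total_weight(self) -> float:
        lw = self.log_weights
        m = lw.max()
        return float(math.exp(m) * np.exp(lw - m).sum())

    def normalized_weights(self) -> np.ndarray:
        """Weights rescaled to sum to 1, computed stably in log space.

        When the ensemble was grown as independent islands
        (``family_ids`` set), each island is self-normalized and islands
        receive equal mass: the equal-replicate combination avoids the
        high-variance (and estimate-correlated) weighting that island
        normalizing-constant estimates would otherwise introduce.
        """
        lw = self.log_weights
        if self.family_ids is None:
            w = np.exp(lw - lw.max())
            return w / w.sum()
        out = np.zeros(len(lw))
        fams = np.unique(self.family_ids)
        for f in fams:
            sel = self.family_ids == f
            w = np.exp(lw[sel] - lw[sel].max())
            out[sel] = w / w.sum() / len(fams)
        return out

    def effective_sample_size(self) -> float:
        """(sum w)^2 / sum w^2 — equally-weighted samples the ensemble is worth."""
        w = self.normalized_weights()
        return float(1.0 / (w ** 2).sum())

    def unit_coordinate_stack(self) -> np.ndarray:
        """(n_chains, N, 3) array of unit-boundary bead coordinates."""
        return np.stack([c.unit_coordinates for c in self.conformations])

    def subset(self, indices: Sequence[int]) -> "WeightedEnsemble":
        indices = np.asarray(indices, dtype=int)
        return WeightedEnsemble(
            conformations=[self.conformations[i] for i in indices],
            n_units=self.n_units,
            confinement_diameter_um=self.confinement_diameter_um,
            params=self.params,
            attrition_count=self.attrition_count,
            master_seed=self.master_seed,
            family_ids=None if self.family_ids is None
            else self.family_ids[indices],
        )

    def bootstrap_indices(self, rng: np.random.Generator) -> np.ndarray:
        """One bootstrap resample of chain indices.

        Independent chains resample individually; chains grown with
        population resampling resample by genealogy family, since members
        of one family share ancestral segments and are not independent.
        """
        n = len(self.conformations)
        if self.family_ids is None:
            return rng.integers(0, n, size=n)
        fams = np.unique(self.family_ids)
        pick = rng.choice(fams, size=len(fams), replace=True)
        return np.concatenate(
            [np.flatnonzero(self.family_ids == f) for f in pick])


def check_self_avoidance(conf: Conformation,
                         params: Optional[ModelParameters] = None,
                         tol: float = DISTANCE_TOL):
    """Verify the excluded-volume condition.

    Returns ``(ok, violating_pairs)`` where a violating pair is a non-bonded
    bead pair (|i - j| >= 2) whose centre distance falls below
    ``bead_diameter_nm - tol``.  Bonded neighbours sit at exactly one bead
    diameter by construction and are exempt.
    """
    params = params or conf.params
    x = conf.coordinates
    if x.shape[0] < 2:
        return True, []
    tree = cKDTree(x)
    pairs = tree.query_pairs(r=params.bead_diameter_nm - tol, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) >= 2]
    violations = [tuple(int(v) for v in p) for p in pairs]
    return len(violations) == 0, sorted(violations)


def check_confinement(conf: Conformation,
                      D_um: Optional[float] = None,
                      params: Optional[ModelParameters] = None,
                      tol: float = DISTANCE_TOL) -> bool:
    """True iff every bead lies entirely inside the confinement sphere.

    The sphere is centred at the origin; a bead of diameter d_f is inside
    when its centre is within ``D/2 - d_f/2`` of the centre.  ``D_um=None``
    (unconfined) is vacuously true.
    """
    params = params or conf.params
    if D_um is None:
        D_um = conf.confinement_diameter_um
    if D_um is None or math.isinf(D_um):
        return True
    D_nm = D_um * 1000.0
    if D_nm <= params.bead_diameter_nm:
        raise ConfigurationError("confinement diameter must exceed the bead diameter")
    r_allow = D_nm / 2.0 - params.bead_diameter_nm / 2.0
    r = np.linalg.norm(conf.coordinates, axis=1)
    return bool(np.all(r <= r_allow + tol))
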