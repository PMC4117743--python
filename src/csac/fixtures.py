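"""Deterministic geometric fixture conformations with closed-form properties.

These are hand-built chains used throughout the test suite and available
from the CLI: a straight rod, a hairpin with a known number of cross-arm
contacts, a dense snake-packed ball, and a mixed two-family set.  They are
valid chains (consecutive beads one diameter apart, self-avoiding) but are
constructed, not sampled; their weights are 1.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np

from .model import Conformation, ModelParameters, DEFAULT_PARAMS, bead_count

__all__ = ["rod", "hairpin", "dense_ball", "two_family"]


def rod(n_units: int, params: ModelParameters = DEFAULT_PARAMS,
        origin=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)) -> Conformation:
    """Fully extended chain along ``axis``: end-to-end = (N-1) * L_p."""
    n_beads = bead_count(n_units, params)
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    coords = np.asarray(origin, float) + np.outer(
        np.arange(n_beads) * params.bead_diameter_nm, u)
    return Conformation(coordinates=coords, n_units=n_units, log_weight=0.0,
                        confinement_diameter_um=None, seed=0, params=params)


def hairpin(arm_units: int, params: ModelParameters = DEFAULT_PARAMS) -> Conformation:
    """One fold: an outbound arm, one perpendicular unit, a return arm.

    The two arms run antiparallel at a gap of exactly one persistence
    length, so boundary beads facing each other across the fold are
    exactly ``L_p`` apart: with a contact radius of ``L_p`` (plus slack)
    the number of facing boundary-bead pairs is ``arm_units``.
    """
    if arm_units < 1:
        raise ValueError("arm_units must be >= 1")
    bpu = params.beads_per_unit
    d = params.bead_diameter_nm
    lp = params.persistence_length_nm
    pts = []
    # outbound arm: units 0..arm_units along +x at y=0
    for b in range(arm_units * bpu + 1):
        pts.append((b * d, 0.0, 0.0))
    # turn unit: straight up in +y
    xmax = arm_units * lp
    for b in range(1, bpu + 1):
        pts.append((xmax, b * d, 0.0))
    # return arm: back along -x at y=L_p
    for b in range(1, arm_units * bpu + 1):
        pts.append((xmax - b * d, lp, 0.0))
    coords = np.array(pts)
    n_units = 2 * arm_units + 2
    assert coords.shape[0] == bead_count(n_units, params)
    return Conformation(coordinates=coords, n_units=n_units, log_weight=0.0,
                        confinement_diameter_um=None, seed=0, params=params)


def dense_ball(n_units: int, params: ModelParameters = DEFAULT_PARAMS,
               origin=(0.0, 0.0, 0.0)) -> Conformation:
    """Chain snake-packed on a cubic lattice of edge = one bead diameter.

    Consecutive beads are exactly one diameter apart, non-bonded beads at
    least one diameter, and the whole chain of ``n`` beads fits inside a
    sphere of diameter ``(m - 1) * d_f * sqrt(3) + d_f`` where
    ``m = ceil(n^(1/3))`` — e.g. 196 beads (40 units) fit well inside
    500 nm.
    """
    n_beads = bead_count(n_units, params)
    d = params.bead_diameter_nm
    m = int(math.ceil(n_beads ** (1.0 / 3.0)))
    pts = []
    count = 0
    for z in range(m):
        for yy in range(m):
            y = yy if z % 2 == 0 else m - 1 - yy
            xs = range(m) if (z * m + yy) % 2 == 0 else range(m - 1, -1, -1)
            for x in xs:
                pts.append((x * d, y * d, z * d))
                count += 1
                if count == n_beads:
                    break
            if count == n_beads:
                break
        if count == n_beads:
            break
    coords = np.array(pts) + np.asarray(origin, float)
    coords -= coords.mean(axis=0) - np.asarray(origin, float)
    return Conformation(coordinates=coords, n_units=n_units, log_weight=0.0,
                        confinement_diameter_um=None, seed=0, params=params)


def two_family(n_rods: int, n_balls: int, n_units: int = 40,
               params: ModelParameters = DEFAULT_PARAMS,
               jitter_nm: float = 1.0, seed: int = 0,
               ) -> Tuple[List[Conformation], List[str]]:
    """Mixed extended and compact chains with known family labels.

    A small deterministic coordinate jitter (kept well below the excluded-
    volume tolerance scale used in clustering, not validity checks) makes
    the members of each family distinct.
    """
    rng = np.random.default_rng(seed)
    confs, labels = [], []
    for _ in range(n_rods):
        c = rod(n_units, params)
        c.coordinates = c.coordinates + rng.normal(0, jitter_nm, c.coordinates.shape)
        confs.append(c)
        labels.append("rod")
    for _ in range(n_balls):
        c = dense_ball(n_units, params)
        c.coordinates = c.coordinates + rng.normal(0, jitter_nm, c.coordinates.shape)
        confs.append(c)
        labels.append("ball")
    return confs, labels
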