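"""Conformation file I/O and run configuration.

Ensembles are stored as concatenated extended-XYZ frames: an atom-count
line, a ``key=value`` comment line carrying the chain metadata (chain id,
N, D, log-weight, seed, fiber parameters), then one ``C x y z`` record per
bead with coordinates in nm at fixed 1e-4 nm precision.  A companion CSV
manifest lists per-chain ids, weights and the ensemble attrition count.
Extended-XYZ is used instead of PDB because nm-scale coordinates inside a
micrometre sphere overflow PDB's fixed-width fields; a PDB export (in Å
after a 1/10 scale) is provided for visualization only.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .model import (Conformation, ModelParameters, ValidationError,
                    WeightedEnsemble, check_confinement, check_self_avoidance)

__all__ = [
    "write_conformations",
    "read_conformations",
    "write_pdb",
    "RunConfig",
    "load_config",
    "save_config",
]

_COORD_FMT = "%.4f"


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.csv")


def write_conformations(ensemble: WeightedEnsemble,
                        path: Union[str, Path],
                        manifest: bool = True) -> Path:
    """Write an ensemble as concatenated extended-XYZ frames (+ manifest)."""
    path = Path(path)
    p = ensemble.params
    d_um = ensemble.confinement_diameter_um
    with open(path, "w") as fh:
        for i, conf in enumerate(ensemble):
            fh.write(f"{conf.n_beads}\n")
            fh.write(
                f"chain_id={i} n_units={conf.n_units} "
                f"d_um={'free' if d_um is None else repr(float(d_um))} "
                f"log_weight={conf.log_weight!r} seed={conf.seed} "
                f"bead_diameter_nm={p.bead_diameter_nm!r} "
                f"persistence_length_nm={p.persistence_length_nm!r} "
                f"bp_per_bead={p.bp_per_bead!r} k_states={p.k_states} "
                f"contact_radius_nm={p.contact_radius_nm!r}\n")
            for x, y, z in conf.coordinates:
                fh.write(f"C {_COORD_FMT % x} {_COORD_FMT % y} {_COORD_FMT % z}\n")
    if manifest:
        pd.DataFrame({
            "chain_id": np.arange(len(ensemble)),
            "log_weight": ensemble.log_weights,
            "seed": [c.seed for c in ensemble],
            "attrition_count": ensemble.attrition_count,
        }).to_csv(_manifest_path(path), index=False)
    return path


def _parse_comment(line: str, frame: int) -> dict:
    out = {}
    for tok in line.split():
        if "=" not in tok:
            raise ValueError(f"frame {frame}: malformed comment token {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def read_conformations(path: Union[str, Path],
                       validate: bool = True) -> WeightedEnsemble:
    """Read an extended-XYZ ensemble written by :func:`write_conformations`.

    With ``validate=True`` every chain is checked for self-avoidance and
    confinement; violations raise :class:`ValidationError` listing the
    offending chain ids.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    confs: List[Conformation] = []
    params: Optional[ModelParameters] = None
    d_um: Optional[float] = None
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_beads = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame} (line {i+1}): expected atom count, "
                             f"got {lines[i]!r}") from exc
        if i + 1 + n_beads >= len(lines) + 1 and False:
            pass
        if i + 1 >= len(lines):
            raise ValueError(f"frame {frame}: truncated after atom count")
        meta = _parse_comment(lines[i + 1], frame)
        try:
            kv_d = meta["d_um"]
            d_um = None if kv_d == "free" else float(kv_d)
            params = ModelParameters(
                bead_diameter_nm=float(meta["bead_diameter_nm"]),
                persistence_length_nm=float(meta["persistence_length_nm"]),
                bp_per_bead=float(meta["bp_per_bead"]),
                k_states=int(meta["k_states"]),
                contact_radius_nm=float(meta["contact_radius_nm"]),
                confinement_diameter_um=d_um if d_um else 1.5)
            n_units = int(meta["n_units"])
            log_weight = float(meta["log_weight"])
            seed = int(meta["seed"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"frame {frame} (line {i+2}): bad metadata: {exc}") from exc
        rows = lines[i + 2:i + 2 + n_beads]
        if len(rows) < n_beads:
            raise ValueError(f"frame {frame}: truncated, expected {n_beads} "
                             f"bead records, found {len(rows)}")
        coords = np.empty((n_beads, 3))
        for j, row in enumerate(rows):
            parts = row.split()
            if len(parts) != 4:
                raise ValueError(f"frame {frame} (line {i+3+j}): malformed bead "
                                 f"record {row!r}")
            coords[j] = [float(v) for v in parts[1:]]
        confs.append(Conformation(coordinates=coords, n_units=n_units,
                                  log_weight=log_weight,
                                  confinement_diameter_um=d_um,
                                  seed=seed, params=params))
        i += 2 + n_beads
        frame += 1
    if not confs:
        raise ValueError(f"{path}: no frames found")

    attrition = 0
    mpath = _manifest_path(path)
    if mpath.exists():
        man = pd.read_csv(mpath)
        if len(man):
            attrition = int(man["attrition_count"].iloc[0])
    ens = WeightedEnsemble(conformations=confs, n_units=confs[0].n_units,
                           confinement_diameter_um=d_um, params=params,
                           attrition_count=attrition)
    if validate:
        # round-tripped coordinates carry 1e-4 nm quantization noise
        bad = [i for i, c in enumerate(confs)
               if not check_self_avoidance(c, params, tol=1e-3)[0]
               or not check_confinement(c, d_um, params, tol=1e-3)]
        if bad:
            raise ValidationError(f"chains violate model invariants: {bad}")
    return ens


def write_pdb(conf: Conformation, path: Union[str, Path]) -> Path:
    """Visualization-only PDB export (coordinates in Å after 1/10 scale)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(conf.coordinates / 10.0, start=1):
            serial = i % 100000
            fh.write(f"ATOM  {serial:5d}  CA  GLY A{(i % 10000):4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")
    return path


@dataclasses.dataclass
class RunConfig:
    """Complete, serializable description of one simulation/analysis run."""

    model: ModelParameters = dataclasses.field(default_factory=ModelParameters)
    n_chains: int = 100
    n_units: int = 1000
    confinement_um: Optional[float] = 1.5  # None = free space
    seed: int = 0
    s_grid_points: int = 120
    nu_fit_range: Tuple[float, float] = (5.0, 25.0)
    alpha_fit_range: Tuple[float, float] = (5.0, 125.0)
    n_boot: int = 1000
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = dataclasses.asdict(self.model)
        d["nu_fit_range"] = list(self.nu_fit_range)
        d["alpha_fit_range"] = list(self.alpha_fit_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = ModelParameters(**d["model"])
        for k in ("nu_fit_range", "alpha_fit_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def save_config(cfg: RunConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path


def load_config(path: Union[str, Path]) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
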