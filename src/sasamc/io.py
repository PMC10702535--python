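"""Configuration, trajectory I/O, run manifests and seeded synthetic
data generators."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as c
from .cg_model import MoleculeTemplate, BeadSpec, build_caffeine_template
from .sasa_potential import SaltField
from .mc_engine import MoveParams, RunProtocol, SystemState

__all__ = [
    "load_config",
    "dump_config",
    "write_xyz",
    "read_xyz",
    "write_manifest",
    "generate_synthetic_osm_table",
    "generate_toy_system",
    "template_to_dict",
    "template_from_dict",
]

# Schema: key -> (default, type).  Defaults follow the printed protocol
# constants of the caffeine study.
_SCHEMA = {
    "ensemble": ("canonical", str),
    "temperature": (c.T_DEFAULT, float),
    "box_length": (250.0, float),
    "n_molecules": (200, int),
    "activity": (None, float),
    "salt_label": ("none", str),
    "salt_concentration": (0.0, float),
    "tfe": (0.0, float),
    "surface_tension": (c.GAMMA_CALIBRATED, float),
    "probe_radius": (c.PROBE_RADIUS_DEFAULT, float),
    "equilibration": (5_000, int),
    "production": (50_000, int),
    "sample_stride": (10, int),
    "rdf_bin_width": (0.25, float),
    "widom_inserts": (25, int),
    "volume_perturbation": (5.0, float),
    "max_translation": (2.5, float),
    "max_rotation": (0.5, float),
    "cluster_translation": (7.5, float),
    "cluster_rotation": (1.0, float),
    "cluster_threshold": (6.5, float),
    "weight_cluster": (0.2, float),
    "seed": (1, int),
}


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected; missing keys are filled with the
    defaults above (canonical protocol of the caffeine study).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None or not isinstance(data, dict):
        raise ValueError(f"empty or non-mapping config file: {path}")
    unknown = sorted(set(data) - set(_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = {}
    for key, (default, typ) in _SCHEMA.items():
        val = data.get(key, default)
        if val is not None:
            try:
                val = typ(val)
            except (TypeError, ValueError) as err:
                raise ValueError(f"config key {key!r}: {err}") from None
        cfg[key] = val
    if cfg["ensemble"] not in ("canonical", "grand_canonical"):
        raise ValueError(f"unknown ensemble {cfg['ensemble']!r}")
    if cfg["ensemble"] == "grand_canonical" and cfg["activity"] is None:
        raise ValueError("grand_canonical config requires 'activity'")
    return cfg


def dump_config(cfg: dict, path):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_to_objects(cfg: dict):
    """Build (template, state, moves, protocol, salt) from a config."""
    template = build_caffeine_template(
        probe_radius=cfg["probe_radius"],
        surface_tension=cfg["surface_tension"], tfe=cfg["tfe"])
    salt = SaltField(c_s=cfg["salt_concentration"], label=cfg["salt_label"])
    rng = np.random.default_rng(cfg["seed"])
    state = SystemState.random(
        template, cfg["box_length"], cfg["n_molecules"], rng=rng,
        temperature=cfg["temperature"], salt=salt, ensemble=cfg["ensemble"],
        activity=cfg["activity"])
    gc = cfg["ensemble"] == "grand_canonical"
    moves = MoveParams(
        max_translation=10.0 if gc else cfg["max_translation"],
        max_rotation=1.0 if gc else cfg["max_rotation"],
        cluster_translation=cfg["cluster_translation"],
        cluster_rotation=cfg["cluster_rotation"],
        cluster_threshold=cfg["cluster_threshold"],
        weight_cluster=0.0 if gc else cfg["weight_cluster"],
        weight_gc=1.0 if gc else 0.0)
    protocol = RunProtocol(equilibration=cfg["equilibration"],
                           production=cfg["production"], seed=cfg["seed"],
                           sample_stride=cfg["sample_stride"])
    return template, state, moves, protocol, salt


# -- trajectories -------------------------------------------------------

def write_xyz(frames, path, template: MoleculeTemplate):
    """Write bead pseudo-atom frames to an XYZ file.

    Each frame is (box_length, com (n,3), offsets (n,nb,3)); the element
    field carries the bead label, the comment line the box length and
    frame index."""
    names = template.names
    with open(path, "w") as fh:
        for idx, (L, com, off) in enumerate(frames):
            n = com.shape[0]
            fh.write(f"{n * len(names)}\n")
            fh.write(f"frame={idx} box={L:.6f}\n")
            for i in range(n):
                for b, name in enumerate(names):
                    x, y, z = com[i] + off[i][b]
                    fh.write(f"{name} {x:.5f} {y:.5f} {z:.5f}\n")


def read_xyz(path):
    """Read an XYZ trajectory written by :func:`write_xyz`; returns a
    list of (box_length, labels, coords)."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from None
        comment = lines[i + 1]
        box = None
        for tok in comment.split():
            if tok.startswith("box="):
                box = float(tok[4:])
        labels, coords = [], []
        for j in range(count):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: malformed atom line")
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append((box, labels, np.array(coords)))
        i += 2 + count
    return frames


def write_manifest(out_dir, cfg: dict, extra=None):
    """Write the run manifest (parameter echo, seed, code version,
    timestamps, input checksums)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": cfg,
        "seed": cfg.get("seed"),
        "code_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_checksum": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# -- template serialization ---------------------------------------------

def template_to_dict(template: MoleculeTemplate) -> dict:
    return {
        "beads": [
            {"name": b.name, "position": list(map(float, b.position)),
             "sasa_radius": b.sasa_radius, "wca_sigma": b.wca_sigma,
             "wca_epsilon": b.wca_epsilon,
             "surface_tension": b.surface_tension, "tfe": b.tfe}
            for b in template.beads
        ]
    }


def template_from_dict(data: dict) -> MoleculeTemplate:
    beads = tuple(
        BeadSpec(name=b["name"], position=np.asarray(b["position"], float),
                 sasa_radius=b["sasa_radius"], wca_sigma=b["wca_sigma"],
                 wca_epsilon=b["wca_epsilon"],
                 surface_tension=b.get("surface_tension", 0.0),
                 tfe=b.get("tfe", 0.0))
        for b in data["beads"])
    return MoleculeTemplate(beads=beads)


# -- synthetic data -----------------------------------------------------

def generate_synthetic_osm_table(C1, C2, seed,
                                 m2_grid=(0.010, 0.025, 0.050, 0.075),
                                 m3_grid=(0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
                                 noise_sigma: float = 0.0,
                                 caffeine_binary=(-7.2399, 24.9741),
                                 salt_binary=(0.0, 0.0), nu3: int = 2,
                                 label: str = "salt") -> pd.DataFrame:
    """Seeded synthetic osmometry table with the residual structure
    ΔOsm = (C₁ + C₂·m₂)·m₂·m₃ plus Gaussian noise.

    Binary osmolalities come from the Gibbs-Duhem surface of an
    activity model with the given binary coefficients (defaults: the
    caffeine self-association coefficients and an ideal salt); the grid
    mirrors the experimental design (fixed caffeine molalities 10-75
    mmol/kg, salt molality up to 0.5 mol/kg).
    """
    from .thermo_kb import ActivityModel, SolutionComposition, osmolality
    from .vpo_analysis import OsmTable

    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    model = ActivityModel(A2=caffeine_binary[0], B2=caffeine_binary[1],
                          C1=C1, C2=C2, A3=salt_binary[0], B3=salt_binary[1],
                          nu3=nu3)
    rows = []
    for m2 in np.concatenate([[0.0], np.asarray(m2_grid, float)]):
        for m3 in np.concatenate([[0.0], np.asarray(m3_grid, float)]):
            if m2 == 0 and m3 == 0:
                continue
            osm = osmolality(SolutionComposition(m2, m3), model)
            if noise_sigma > 0:
                osm = max(osm + rng.normal(0.0, noise_sigma), 0.0)
            rows.append(dict(m2=m2, m3=m3, osm=osm,
                             stderr=noise_sigma, label=label))
    return OsmTable(rows)


def generate_toy_system(kind: str, seed: int = 0, **params):
    """Reproducible toy systems for estimator validation.

    Kinds: ``ideal`` (point particles, no interactions), ``wca`` (single
    purely repulsive bead per molecule), ``dimer`` (two molecules at a
    prescribed separation along x).
    """
    rng = np.random.default_rng(seed)
    if kind == "ideal":
        n = params.get("n", 100)
        L = params.get("box_length", 60.0)
        tpl = MoleculeTemplate((BeadSpec("X", np.zeros(3), 1e-3, 1e-3,
                                         1e-12),))
        return SystemState.random(tpl, L, n, rng=rng,
                                  **{k: v for k, v in params.items()
                                     if k in ("ensemble", "activity",
                                              "temperature")})
    if kind == "wca":
        n = params.get("n", 50)
        L = params.get("box_length", 60.0)
        sigma = params.get("sigma", 4.0)
        eps = params.get("epsilon", 0.5)
        tpl = MoleculeTemplate((BeadSpec("W", np.zeros(3), sigma / 2.0,
                                         sigma, eps),))
        return SystemState.random(tpl, L, n, rng=rng,
                                  **{k: v for k, v in params.items()
                                     if k in ("ensemble", "activity",
                                              "temperature")})
    if kind == "dimer":
        separation = params.get("separation", 7.0)
        axis = np.asarray(params.get("axis", (1.0, 0.0, 0.0)), dtype=float)
        axis = axis / np.linalg.norm(axis)
        L = params.get("box_length", 60.0)
        tpl = params.get("template") or build_caffeine_template()
        state = SystemState(tpl, L, n=2,
                            temperature=params.get("temperature", c.T_DEFAULT))
        body = tpl.body_coords
        state.com[0] = np.array([L / 2, L / 2, L / 2])
        state.com[1] = state.com[0] + separation * axis
        state.offsets[0] = body
        state.offsets[1] = body
        return state
    raise ValueError(f"unknown toy-system kind {kind!r}")
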