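"""End-to-end orchestration: parameterize -> sample -> energize -> walk -> stats.

One declarative YAML config drives the whole run; every stage persists its
artifact under the output directory and records a sha256 checksum in the run
manifest, so a rerun on an unchanged config skips completed stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .energies import EnergyContext, build_energy_table, load_energy_csv
from .errors import ConfigError
from .fixtures import FixtureSpec, build_fixture, emit_fixture
from .sampling import LatticeFrame, generate_lattice
from .solver import PBPhysics
from .structures import assign_parameters, read_pdb
from .walker import MCConfig, ensemble_stats, run_ensemble

logger = logging.getLogger(__name__)

#: documented defaults for every optional config key
DEFAULTS = {
    "pb": {
        "eps_in": 2.0,
        "eps_out": 80.0,
        "ionic_strength": 0.150,
        "temperature": 298.15,
        "stern": 2.0,
        "tol": 1e-6,
        "parent_resolution": 0.5,
        "child_resolution": 2.0,
        "parent_edge": None,
    },
    "energy": {"method": "pairwise", "clamp": 1.0, "eps_coulomb": None, "workers": 1},
    "mc": {
        "temperature": 500.0,
        "n_pathways": 1000,
        "termination_distance": 80.0,
        "max_steps": 10_000_000,
        "seed": 0,
        "start_index": None,
    },
}

_KNOWN_TOP = {"receptor", "ligand", "pb", "lattice", "energy", "mc", "output_dir"}
_KNOWN_SUB = {
    "receptor": {"pdb", "forcefield", "fixture", "allow_defaults"},
    "ligand": {"pdb", "forcefield", "fixture", "allow_defaults"},
    "pb": set(DEFAULTS["pb"]),
    "lattice": {"geometry", "frame", "ranges", "steps", "rotamers"},
    "energy": set(DEFAULTS["energy"]),
    "mc": set(DEFAULTS["mc"]),
}


@dataclass
class RunConfig:
    """A validated, fully defaulted run configuration."""

    receptor: dict
    ligand: dict
    lattice: dict
    output_dir: str
    pb: dict = field(default_factory=dict)
    energy: dict = field(default_factory=dict)
    mc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(source) -> RunConfig:
    """Parse + validate a config (path, YAML string, or dict).

    All defaults are filled in; every violation found is reported in one
    aggregated :class:`ConfigError`.
    """
    if isinstance(source, (str, Path)):
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        raw = yaml.safe_load(Path(source).read_text() if is_file else str(source))
    else:
        raw = copy.deepcopy(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    errors = []
    for key in raw:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown top-level key {key!r}")
    for key, allowed in _KNOWN_SUB.items():
        sub = raw.get(key)
        if isinstance(sub, dict):
            for k in sub:
                if k not in allowed:
                    errors.append(f"unknown key {key}.{k!r}")

    for req in ("receptor", "ligand", "lattice", "output_dir"):
        if req not in raw:
            errors.append(f"missing required key {req!r}")

    merged = {}
    for sect in ("pb", "energy", "mc"):
        merged[sect] = dict(DEFAULTS[sect], **(raw.get(sect) or {}))

    for body in ("receptor", "ligand"):
        spec = raw.get(body)
        if not isinstance(spec, dict):
            if body in raw:
                errors.append(f"{body} must be a mapping")
            continue
        if "fixture" not in spec and "pdb" not in spec:
            errors.append(f"{body}: needs either 'fixture' or 'pdb'")
        if "pdb" in spec and "forcefield" not in spec:
            errors.append(f"{body}: 'pdb' input needs a 'forcefield' table")

    lattice = raw.get("lattice")
    if isinstance(lattice, dict):
        if "geometry" not in lattice:
            errors.append("lattice: missing 'geometry'")
        elif lattice["geometry"] not in ("cuboidal", "spherical", "cylindrical"):
            errors.append(f"lattice: unknown geometry {lattice['geometry']!r}")

    if merged["mc"]["temperature"] is not None and merged["mc"]["temperature"] <= 0:
        errors.append("mc.temperature must be > 0")
    if merged["mc"]["termination_distance"] <= 0:
        errors.append("mc.termination_distance must be > 0")
    if merged["mc"]["n_pathways"] < 1:
        errors.append("mc.n_pathways must be >= 1")
    if merged["pb"]["ionic_strength"] < 0:
        errors.append("pb.ionic_strength must be >= 0")
    if merged["energy"]["method"] not in ("pairwise", "field"):
        errors.append(f"energy.method must be 'pairwise' or 'field'")

    # cross-field: a finite parent box must cover the sampling region
    if (
        merged["energy"]["method"] == "field"
        and merged["pb"]["parent_edge"] is not None
        and isinstance(lattice, dict)
    ):
        half = merged["pb"]["parent_edge"] / 2.0
        for name, rng in (lattice.get("ranges") or {}).items():
            lo, hi = (rng, rng) if np.isscalar(rng) else (rng[0], rng[1])
            if name in ("x", "y", "z", "longitudinal", "radial", "r") and max(
                abs(lo), abs(hi)
            ) > half:
                errors.append(
                    f"lattice range {name!r} ({lo}..{hi} Å) extends past the "
                    f"PB parent box (half-edge {half} Å)"
                )

    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    return RunConfig(
        receptor=raw["receptor"],
        ligand=raw["ligand"],
        lattice=raw["lattice"],
        output_dir=str(raw["output_dir"]),
        pb=merged["pb"],
        energy=merged["energy"],
        mc=merged["mc"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _load_body(spec: dict, outdir: Path, stem: str):
    if "fixture" in spec:
        f = dict(spec["fixture"])
        kind = f.pop("kind")
        seed = int(f.pop("seed", 0))
        structure = build_fixture(FixtureSpec.make(kind, seed=seed, **f))
        emit_fixture(structure, outdir, stem=stem)
        return structure
    structure = read_pdb(spec["pdb"])
    return assign_parameters(
        structure, spec["forcefield"], allow_defaults=bool(spec.get("allow_defaults"))
    )


def _build_lattice(cfg: dict):
    frame_cfg = cfg.get("frame") or {}
    frame = LatticeFrame(
        origin=tuple(frame_cfg.get("origin", (0.0, 0.0, 0.0))),
        axes=tuple(
            tuple(a) for a in frame_cfg.get(
                "axes", ((1, 0, 0), (0, 1, 0), (0, 0, 1))
            )
        ),
    )
    rotamers = cfg.get("rotamers", 1)
    if isinstance(rotamers, list):
        rotamers = [tuple(r) for r in rotamers]
    return generate_lattice(
        cfg["geometry"],
        frame=frame,
        ranges={k: tuple(v) if not np.isscalar(v) else v for k, v in (cfg.get("ranges") or {}).items()},
        steps=cfg.get("steps") or {},
        rotamers=rotamers,
    )


def run_pipeline(config: RunConfig, resume: bool = True) -> dict:
    """Execute all five stages; returns (and persists) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "run_manifest.json"
    manifest = {"stages": {}, "config_hash": _config_hash(config.to_dict())}
    previous = {}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            previous = old.get("stages", {})

    def stage_done(name, inputs_hash):
        st = previous.get(name)
        if not st or st.get("inputs_hash") != inputs_hash:
            return None
        for p, digest in st.get("artifacts", {}).items():
            fp = Path(p)
            if not fp.exists() or _sha256(fp) != digest:
                return None
        return st

    def record(name, inputs_hash, artifacts, extra=None):
        manifest["stages"][name] = {
            "inputs_hash": inputs_hash,
            "artifacts": {str(p): _sha256(Path(p)) for p in artifacts},
            **(extra or {}),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    t0 = time.time()

    # stage 1: parameterize -------------------------------------------------
    h1 = _config_hash([config.receptor, config.ligand])
    receptor = _load_body(config.receptor, outdir, "receptor")
    ligand = _load_body(config.ligand, outdir, "ligand")
    st = stage_done("parameterize", h1)
    if st:
        manifest["stages"]["parameterize"] = st
    else:
        logger.info("stage parameterize: receptor %d atoms (net %+.3f e), ligand %d atoms (net %+.3f e)",
                    receptor.n_atoms, receptor.net_charge, ligand.n_atoms, ligand.net_charge)
        arts = [p for p in outdir.glob("receptor.*")] + [p for p in outdir.glob("ligand.*")]
        record("parameterize", h1, arts,
               {"receptor_net_charge": receptor.net_charge, "ligand_net_charge": ligand.net_charge})

    # stage 2: sample -------------------------------------------------------
    h2 = _config_hash(config.lattice)
    lattice = _build_lattice(config.lattice)
    lattice_csv = outdir / "lattice.csv"
    if stage_done("sample", h2):
        manifest["stages"]["sample"] = previous["sample"]
    else:
        lattice.to_dataframe().to_csv(lattice_csv, index=False, float_format="%.10g")
        logger.info("stage sample: %d stations x %d rotamers = %d poses",
                    lattice.n_stations, lattice.n_rotamers, lattice.n_poses)
        record("sample", h2, [lattice_csv], {"n_poses": lattice.n_poses})

    # stage 3: energize -----------------------------------------------------
    h3 = _config_hash([h1, h2, config.energy, config.pb])
    energies_csv = outdir / "energies.csv"
    st = stage_done("energize", h3)
    if st and energies_csv.exists():
        manifest["stages"]["energize"] = st
        table = load_energy_csv(lattice, energies_csv)
    else:
        physics = PBPhysics(
            eps_in=config.pb["eps_in"],
            eps_out=config.pb["eps_out"],
            ionic_strength=config.pb["ionic_strength"],
            temperature=config.pb["temperature"],
            stern=config.pb["stern"],
        )
        context = EnergyContext(
            physics=physics,
            clamp=config.energy["clamp"],
            eps_coulomb=config.energy["eps_coulomb"],
            parent_resolution=config.pb["parent_resolution"],
            parent_edge=config.pb["parent_edge"],
            child_resolution=config.pb["child_resolution"],
            tol=config.pb["tol"],
        )
        table = build_energy_table(
            receptor, ligand, lattice,
            method=config.energy["method"],
            context=context,
            workers=int(config.energy["workers"]),
        )
        table.to_csv(energies_csv)
        logger.info("stage energize: %d records, e_total range [%.3f, %.3f] kcal/mol",
                    lattice.n_poses, table.e_total.min(), table.e_total.max())
        record("energize", h3, [energies_csv])

    # stage 4: walk ---------------------------------------------------------
    h4 = _config_hash([h3, config.mc])
    pathways_csv = outdir / "pathways.csv"
    start = config.mc["start_index"]
    if start is None:
        start = _default_start(lattice)
    mc = MCConfig(
        start_index=tuple(int(v) for v in start),
        temperature=config.mc["temperature"],
        termination_distance=config.mc["termination_distance"],
        max_steps=int(config.mc["max_steps"]),
        seed=int(config.mc["seed"]),
    )
    st = stage_done("walk", h4)
    rerun_walk = not (st and pathways_csv.exists())
    if rerun_walk:
        pathways = run_ensemble(table, mc, int(config.mc["n_pathways"]))
        rows = ["pathway,outcome,length,accepted,attempted,final_flat_index"]
        for i, p in enumerate(pathways):
            rows.append(f"{i},{p.outcome},{p.length},{p.accepted},{p.attempted},{p.states[-1]}")
        pathways_csv.write_text("\n".join(rows) + "\n")
        logger.info("stage walk: %d pathways, mean length %.0f", len(pathways),
                    sum(p.length for p in pathways) / len(pathways))
        record("walk", h4, [pathways_csv])
    else:
        manifest["stages"]["walk"] = st
        pathways = None

    # stage 5: stats --------------------------------------------------------
    h5 = _config_hash([h4])
    stats_json = outdir / "ensemble_stats.json"
    st = stage_done("stats", h5)
    if st and stats_json.exists() and pathways is None:
        manifest["stages"]["stats"] = st
    else:
        if pathways is None:
            pathways = run_ensemble(table, mc, int(config.mc["n_pathways"]))
        stats = ensemble_stats(pathways, lattice)
        payload = stats.to_dict()
        payload["occupancy"] = stats.occupancy.tolist()
        stats_json.write_text(json.dumps(payload, indent=2))
        logger.info("stage stats: p_plus = %.3f +/- %.3f", stats.p_plus, stats.se_p_plus)
        record("stats", h5, [stats_json], {"p_plus": stats.p_plus})

    manifest["wall_time_s"] = time.time() - t0
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _default_start(lattice) -> tuple:
    """Center of every index dimension: the canonical starting pose."""
    return tuple(n // 2 for n in lattice.shape)
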