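"""Run-configuration schema: YAML loading, validation and object building.

A run config describes one virtual FLIP experiment: geometry (or a
population spec), one diffusing species, a barrier set, the bleach protocol,
the time step and the seed.  Unknown keys are rejected so typos fail fast;
every output file written by the CLI embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .barriers import LipidDomainConfig, PermeablePlane, ProteinRing, preset_domain
from .engine import FlipProtocol, Species
from .geometry import LobeParams, build_ea_geometry, build_la_geometry
from .synthetic_data import PopulationSpec

__all__ = ["ConfigError", "load_config", "config_hash", "build_geometry",
           "build_species", "build_barriers", "build_protocol", "build_run"]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


_TOP_KEYS = {"geometry", "population", "species", "barriers", "protocol",
             "dt", "seed", "output"}
_GEOM_KEYS = {"stage", "mother", "daughter", "bridge_length", "bridge_diameter",
              "perinuclear_thickness_lobe", "perinuclear_thickness_bridge",
              "neck_opening_radius", "n_vertices", "fillet"}
_LOBE_KEYS = {"semi_axis_long", "semi_axis_short", "piriform_scale",
              "piriform_deviation"}
_SPECIES_KEYS = {"name", "enclosure", "D_eff", "D_in_domain", "copy_number",
                 "particle_radius", "excluded_volume", "fluorescence_weight"}
_PROTOCOL_KEYS = {"spot_radius", "spot_length", "placement", "bridge_fraction",
                  "k_bleach", "t_total", "sampling_dt", "loss_fraction"}
_BARRIER_KINDS = {"lipid_domain", "protein_ring", "permeable_plane", "preset"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def load_config(path) -> dict:
    """Load and schema-validate a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    if ("geometry" in cfg) == ("population" in cfg):
        raise ConfigError("config needs exactly one of 'geometry' or 'population'")
    if "species" not in cfg:
        raise ConfigError("config needs a 'species' section")
    if "geometry" in cfg:
        geom = cfg["geometry"]
        _check_keys(geom, _GEOM_KEYS, "geometry")
        for lobe in ("mother", "daughter"):
            if lobe not in geom:
                raise ConfigError(f"geometry needs a '{lobe}' block")
            _check_keys(geom[lobe], _LOBE_KEYS, f"geometry.{lobe}")
        if geom.get("stage") not in ("EA", "LA"):
            raise ConfigError("geometry.stage must be 'EA' or 'LA'")
        if geom["stage"] == "LA" and "bridge_length" not in geom:
            raise ConfigError("LA geometry needs bridge_length")
    _check_keys(cfg["species"], _SPECIES_KEYS, "species")
    for key in ("name", "enclosure", "D_eff"):
        if key not in cfg["species"]:
            raise ConfigError(f"species needs '{key}'")
    if "protocol" in cfg:
        _check_keys(cfg["protocol"], _PROTOCOL_KEYS, "protocol")
    for i, b in enumerate(cfg.get("barriers", []) or []):
        kind = b.get("kind")
        if kind not in _BARRIER_KINDS:
            raise ConfigError(f"barriers[{i}].kind must be one of {sorted(_BARRIER_KINDS)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def build_geometry(geom: dict):
    stage = geom["stage"]
    mother = LobeParams(**geom["mother"])
    daughter = LobeParams(**geom["daughter"], orientation="daughter")
    common = {k: geom[k] for k in ("n_vertices", "fillet") if k in geom}
    if stage == "EA":
        for k in ("perinuclear_thickness_lobe", "neck_opening_radius"):
            if k in geom:
                common[k] = geom[k]
        return build_ea_geometry(mother, daughter, **common)
    for k in ("bridge_diameter", "perinuclear_thickness_lobe",
              "perinuclear_thickness_bridge"):
        if k in geom:
            common[k] = geom[k]
    return build_la_geometry(mother, daughter, bridge_length=geom["bridge_length"],
                             **common)


def build_species(spec: dict) -> Species:
    return Species(**spec)


def build_barriers(blocks: list | None) -> list:
    out = []
    for b in blocks or []:
        b = dict(b)
        kind = b.pop("kind")
        if kind == "preset":
            name = b.pop("name")
            out.append(preset_domain(name, **b))
        elif kind == "lipid_domain":
            out.append(LipidDomainConfig(**b))
        elif kind == "protein_ring":
            out.append(ProteinRing(**b))
        elif kind == "permeable_plane":
            out.append(PermeablePlane(**b))
    return out


def build_protocol(proto: dict | None) -> FlipProtocol:
    return FlipProtocol(**(proto or {}))


def build_population(pop: dict) -> PopulationSpec:
    return PopulationSpec(**pop)


def build_run(cfg: dict):
    """Build (geometry, species, barriers, protocol, dt, seed) from a config."""
    if "geometry" not in cfg:
        raise ConfigError("build_run requires a 'geometry' config (not a population)")
    return (build_geometry(cfg["geometry"]), build_species(cfg["species"]),
            build_barriers(cfg.get("barriers")), build_protocol(cfg.get("protocol")),
            float(cfg.get("dt", 4e-5)), int(cfg.get("seed", 0)))
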