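"""Simulation configuration: every knob of the end-to-end simulator, plus the
structured text (YAML) configuration reader and the compatibility parser for
the classic control line ``seqerr = <depth> <error> <a_samples> <a_positions>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .depth import DepthParams, DEPTH_MODELS
from .species import (
    IntrogressionEvent,
    MigrationBand,
    SpeciesNetwork,
    build_preset,
)

__all__ = ["SimulationConfig", "ERROR_MODES", "parse_seqerr", "load_config"]

ERROR_MODES = ("no-err", "hom-err", "het-err", "both-err")


@dataclass
class SimulationConfig:
    """Settings for one replicate dataset.

    ``loci`` (L), ``samples_per_species`` (S, diploid individuals) and
    ``sites`` (N) set the data dimensions.  ``error_rate`` is the per-read
    base-calling error epsilon; ``mean_depth`` is the overall average read
    depth d-bar.  ``a_samples``/``a_positions`` are the beta concentration
    parameters for between-species and between-site depth variation, and
    ``corr_p`` the adjacent-site depth correlation.  ``error_mode`` selects
    which class of genotyping errors is committed to the output.
    """

    loci: int = 40
    samples_per_species: int = 1
    sites: int = 250
    error_rate: float = 0.0
    mean_depth: float = 5.0
    a_samples: float = 500.0
    a_positions: float = 1000.0
    corr_p: float = 0.9
    depth_min: int = 2
    depth_max: int = 100
    error_mode: str = "both-err"
    depth_model: str = "conditional-mean"
    seed: int | None = None

    def validate(self) -> None:
        if self.loci < 1 or self.sites < 1 or self.samples_per_species < 1:
            raise ValueError("loci, sites and samples_per_species must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if not self.depth_min < self.mean_depth < self.depth_max:
            raise ValueError("require depth_min < mean_depth < depth_max")
        if self.error_mode not in ERROR_MODES:
            raise ValueError(f"error_mode must be one of {ERROR_MODES}")
        if self.depth_model not in DEPTH_MODELS:
            raise ValueError(f"depth_model must be one of {DEPTH_MODELS}")
        self.depth_params()  # range checks on the depth side

    def depth_params(self) -> DepthParams:
        return DepthParams(
            mean_depth=self.mean_depth,
            a_samples=self.a_samples,
            a_positions=self.a_positions,
            corr_p=self.corr_p,
            depth_min=self.depth_min,
            depth_max=self.depth_max,
            model=self.depth_model,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def parse_seqerr(line: str) -> tuple[float, float, float, float]:
    """Parse the control line ``seqerr = 5 0.001 500.0 1000.0``.

    Returns (mean_depth, error_rate, a_samples, a_positions).  The bare
    value part (without ``seqerr =``) is accepted too.
    """
    text = line.strip()
    if "=" in text:
        key, _, text = text.partition("=")
        if key.strip() not in ("seqerr", ""):
            raise ValueError(f"not a seqerr line: {line!r}")
    parts = text.split()
    if len(parts) != 4:
        raise ValueError(
            "seqerr expects 4 values: depth, base-calling error, a_samples, a_positions"
        )
    depth, eps, a_s, a_p = (float(v) for v in parts)
    return depth, eps, a_s, a_p


def _network_from_mapping(doc: dict) -> SpeciesNetwork:
    if "preset" in doc:
        return build_preset(doc["preset"], float(doc.get("theta", 0.01)))
    spec = doc["species_tree"]
    intro = [
        IntrogressionEvent(
            donor=e["donor"], recipient=e["recipient"],
            time=float(e["time"]), phi=float(e["phi"]),
        )
        for e in doc.get("introgressions", [])
    ]
    mig = [
        MigrationBand(source=e["source"], dest=e["dest"], rate=float(e["rate"]))
        for e in doc.get("migrations", [])
    ]
    return SpeciesNetwork(
        spec["newick"],
        tau={k: float(v) for k, v in spec["tau"].items()},
        theta=spec["theta"] if not isinstance(spec["theta"], dict)
        else {k: float(v) for k, v in spec["theta"].items()},
        introgressions=intro,
        migrations=mig,
    )


def load_config(path: str | Path) -> tuple[SimulationConfig, SpeciesNetwork]:
    """Read a YAML configuration file describing the network and simulation.

    The ``simulate`` section accepts either explicit keys (``mean_depth``,
    ``error_rate``, ``a_samples``, ``a_positions``) or a verbatim ``seqerr``
    line covering those four.
    """
    doc = yaml.safe_load(Path(path).read_text())
    net = _network_from_mapping(doc)
    sim = dict(doc.get("simulate", {}))
    if "seqerr" in sim:
        depth, eps, a_s, a_p = parse_seqerr(str(sim.pop("seqerr")))
        sim.setdefault("mean_depth", depth)
        sim.setdefault("error_rate", eps)
        sim.setdefault("a_samples", a_s)
        sim.setdefault("a_positions", a_p)
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    config = SimulationConfig(**sim)
    config.validate()
    return config, net
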