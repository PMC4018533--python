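"""Pipeline configuration: defaults, YAML round-trip, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .preprocess import RejectionCriteria
from .spectral import FrequencyGrid
from .synth import BehavioralSpec, CouplingSpec, StudyDesign

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults follow the study constants.

    Analysis window 50-200 ms in 10 ms bins, 1000 trial shuffles, 1000
    bootstrap resamples, 10000 sign-flip permutations, alpha 0.05.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    couplings: list[CouplingSpec] = field(default_factory=list)
    behavioral: BehavioralSpec = field(default_factory=BehavioralSpec)
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    frequency_grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    analysis_window: tuple[float, float] = (50.0, 200.0)
    window_width: float = 10.0
    n_shuffles: int = 1000
    n_boot: int = 1000
    n_perm: int = 10000
    alpha: float = 0.05
    seeds: dict[str, int] = field(
        default_factory=lambda: {"simulate": 1, "equalize": 2, "surrogate": 3, "sem": 4}
    )
    sem_nodes: list[str] = field(default_factory=lambda: ["AC-lh", "TPJ-lh", "vPMC-lh"])
    pairs: list[tuple[str, str]] | None = None
    max_surrogate_tests: int = 3
    equalize_per: str = "cell"  # "cell" (condition x stimulus) or "condition"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis_window"] = list(self.analysis_window)
        d["design"]["epoch_window"] = list(self.design.epoch_window)
        d["couplings"] = [
            {
                **asdict(c),
                "roi_pair": list(c.roi_pair),
                "coupling_window": list(c.coupling_window),
                "conditions": None if c.conditions is None else list(c.conditions),
                "stimulus_types": None if c.stimulus_types is None else list(c.stimulus_types),
            }
            for c in self.couplings
        ]
        d["rejection"]["baseline_window"] = list(self.rejection.baseline_window)
        if self.pairs is not None:
            d["pairs"] = [list(p) for p in self.pairs]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _tuple2(x) -> tuple[float, float]:
    return (float(x[0]), float(x[1]))


def load_config(path: str) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = PipelineConfig()
    if "design" in raw:
        d = dict(raw["design"])
        if "epoch_window" in d:
            d["epoch_window"] = _tuple2(d["epoch_window"])
        cfg.design = StudyDesign(**d)
    if "couplings" in raw:
        cs = []
        for c in raw["couplings"]:
            c = dict(c)
            c["roi_pair"] = tuple(c["roi_pair"])
            if "coupling_window" in c:
                c["coupling_window"] = _tuple2(c["coupling_window"])
            cs.append(CouplingSpec(**c))
        cfg.couplings = cs
    if "behavioral" in raw:
        cfg.behavioral = BehavioralSpec(**raw["behavioral"])
    if "rejection" in raw:
        r = dict(raw["rejection"])
        if "baseline_window" in r:
            r["baseline_window"] = _tuple2(r["baseline_window"])
        cfg.rejection = RejectionCriteria(**r)
    if "frequency_grid" in raw:
        cfg.frequency_grid = FrequencyGrid(**raw["frequency_grid"])
    for key in (
        "window_width",
        "n_shuffles",
        "n_boot",
        "n_perm",
        "alpha",
        "max_surrogate_tests",
        "equalize_per",
        "sem_nodes",
    ):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "analysis_window" in raw:
        cfg.analysis_window = _tuple2(raw["analysis_window"])
    if "seeds" in raw:
        cfg.seeds.update(raw["seeds"])
    if raw.get("pairs"):
        cfg.pairs = [tuple(p) for p in raw["pairs"]]
    return cfg


def save_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)
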