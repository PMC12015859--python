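"""Run configuration: a single serializable object that reproduces a run.

A run is fully determined by the config plus its seed; the global seed fans
out to per-stage, per-subject child streams via ``numpy.random.SeedSequence``
so each subject is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .design import ScheduleTiming, StimulusSpec, ViewingGeometry
from .preprocess import PreprocParams
from .simulate import GroundTruth

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_subjects: int = 3
    n_trials: int = 60
    composition: tuple[int, int, int] = (30, 15, 15)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    timing: ScheduleTiming = field(default_factory=ScheduleTiming)
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    rate: float = 512.0
    out_dir: str = "stereoattn_out"
    write_raw: bool = False           # also write per-subject EDF+ files

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["ground_truth"]["erp_components"] = [
            asdict(c) for c in self.ground_truth.erp_components]
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .simulate import ErpComponentSpec

        raw = yaml.safe_load(Path(path).read_text())
        stim_raw = dict(raw.pop("stimulus", {}))
        if "flicker_freqs_hz" in stim_raw:
            stim_raw["flicker_freqs_hz"] = tuple(stim_raw["flicker_freqs_hz"])
        stimulus = StimulusSpec(**stim_raw)
        geometry = ViewingGeometry(**raw.pop("geometry", {}))
        timing = ScheduleTiming(**raw.pop("timing", {}))
        gt_raw = dict(raw.pop("ground_truth", {}))
        comps = gt_raw.pop("erp_components", None)
        if comps is not None:
            gt_raw["erp_components"] = tuple(
                ErpComponentSpec(**{**c, "topo_centers": tuple(c["topo_centers"])})
                for c in comps)
        if "plane_of_freq" in gt_raw:
            gt_raw["plane_of_freq"] = tuple(
                (float(f), str(p)) for f, p in gt_raw["plane_of_freq"])
        gt = GroundTruth(**gt_raw)
        pp = PreprocParams(**raw.pop("preproc", {}))
        raw["composition"] = tuple(raw.get("composition", (30, 15, 15)))
        return cls(stimulus=stimulus, geometry=geometry, timing=timing,
                   ground_truth=gt, preproc=pp, **raw)
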