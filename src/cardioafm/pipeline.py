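"""End-to-end fibrosis assessment: quantify cohorts, compare groups.

For each tissue sample the pipeline computes three per-sample metrics --
the picrosirius-red positive fraction, the SHG positive fraction, and a
robust summary (median) of the stiffness map -- then runs the group
comparison (omnibus + all pairwise contrasts) once per metric.  On the
default synthetic hidden-fibrosis scenario the AFM metric separates the
far-infarct sections from sham while both collagen stains do not, which
is precisely the sensitivity gap the stiffness route is meant to close.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histology import PSRMaskParams, psr_quantify, shg_quantify
from .stats import ComparisonReport, GroupTable, omnibus_and_pairwise
from .synthetic import TissueSample, gen_tissue_maps_and_images

__all__ = ["FibrosisConfig", "FibrosisReport", "quantify_samples",
           "run_fibrosis_pipeline"]

METRICS = ("afm_median_kpa", "psr_fraction", "shg_fraction")


@dataclass
class FibrosisConfig:
    """Configuration of the fibrosis comparison run.

    ``branch`` may be "auto", "parametric" or "nonparametric" (applied to
    every metric).  With small cohorts a normality screen at the usual
    0.05 demotes a fully normal design to ranks in a substantial share of
    runs while having almost no power against real non-normality, so the
    pipeline screens at a stricter ``normality_alpha`` by default; set
    0.05 to match the generic branch chooser.
    """

    groups: tuple[str, ...] = ("sham_close", "sham_far", "mi_close", "mi_far")
    n_samples: int = 5
    alpha: float = 0.05
    normality_alpha: float = 0.01
    branch: str = "auto"
    afm_summary: str = "median"          # per-sample map statistic
    psr_params: PSRMaskParams = field(default_factory=PSRMaskParams)
    shg_threshold: float | str = "otsu"
    scenario_overrides: dict = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "FibrosisConfig":
        """Load a run configuration from a YAML file.

        Top-level keys mirror the dataclass fields; ``psr_params`` may be
        a mapping of :class:`PSRMaskParams` fields.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if isinstance(raw.get("psr_params"), dict):
            raw["psr_params"] = PSRMaskParams(**raw["psr_params"])
        return cls(**raw)


@dataclass
class FibrosisReport:
    tables: dict[str, GroupTable]
    comparisons: dict[str, ComparisonReport]
    per_sample: pd.DataFrame
    config: FibrosisConfig

    def hidden_fibrosis_detected(self) -> bool:
        """Far-infarct vs sham separates on stiffness but on neither stain."""
        afm = self.comparisons["afm_median_kpa"]
        stains = [self.comparisons["psr_fraction"], self.comparisons["shg_fraction"]]
        afm_hit = all(afm.pair("mi_far", s).significant
                      for s in ("sham_close", "sham_far"))
        stain_quiet = all(not rep.pair("mi_far", s).significant
                          for rep in stains for s in ("sham_close", "sham_far"))
        return bool(afm_hit and stain_quiet)


def quantify_samples(samples: list[TissueSample], config: FibrosisConfig | None = None
                     ) -> pd.DataFrame:
    """Per-sample metric table from raw maps and micrographs."""
    config = config or FibrosisConfig()
    summarize = np.median if config.afm_summary == "median" else np.mean
    rows = []
    for s in samples:
        vals = s.stiffness_map.modulus[s.stiffness_map.valid]
        rows.append({
            "sample": s.sample_id,
            "group": s.group,
            "afm_median_kpa": float(summarize(vals)) / 1e3,
            "psr_fraction": psr_quantify(s.psr, config.psr_params).positive_fraction,
            "shg_fraction": shg_quantify(s.shg, config.shg_threshold).positive_fraction,
        })
    return pd.DataFrame(rows)


def run_fibrosis_pipeline(config: FibrosisConfig | None = None,
                          samples: list[TissueSample] | None = None) -> FibrosisReport:
    """Run the full comparison on synthetic cohorts or supplied samples.

    Without ``samples`` the default hidden-fibrosis scenario is
    simulated (``config.seed`` controls the draw).  Every threshold and
    branch decision ends up in the report.
    """
    config = config or FibrosisConfig()
    if samples is None:
        rng = np.random.default_rng(config.seed)
        samples = []
        for group in config.groups:
            sub = int(rng.integers(0, 2**31 - 1))
            samples.extend(gen_tissue_maps_and_images(
                group, config.n_samples, seed=sub, **config.scenario_overrides))
    per_sample = quantify_samples(samples, config)
    units = {"afm_median_kpa": "kPa", "psr_fraction": "", "shg_fraction": ""}
    tables: dict[str, GroupTable] = {}
    comparisons: dict[str, ComparisonReport] = {}
    for metric in METRICS:
        table = GroupTable(
            data=per_sample[["sample", "group", metric]].rename(columns={metric: "value"}),
            metric=metric, units=units[metric])
        branch = None if config.branch == "auto" else config.branch
        comparisons[metric] = omnibus_and_pairwise(
            table, branch=branch, alpha=config.alpha,
            normality_alpha=config.normality_alpha)
        tables[metric] = table
    return FibrosisReport(tables=tables, comparisons=comparisons,
                          per_sample=per_sample, config=config)
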