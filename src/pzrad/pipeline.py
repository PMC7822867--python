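"""End-to-end driver: simulate -> preprocess -> ADC -> features -> stats -> classify.

Every stage writes its artifact into the output directory together with a
run manifest (config hash, seeds, package version), so identical
configuration and seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import augmentation_tests, hold_one_site_out, results_table
from .features import FEATURE_SETS, build_feature_table
from .stats import association_analysis, anova_site_screen
from .synthetic import CohortConfig, generate_cohort, write_cohort

log = logging.getLogger("pzrad")


@dataclass
class RunConfig:
    """Everything a full run depends on, serializable alongside its outputs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_seed: int = 1
    cv_seed: int = 1
    n_levels: int = 32
    alpha: float = 0.05
    site_screen: bool = True
    feature_sets: list[str] = field(default_factory=lambda: list(FEATURE_SETS))
    write_images: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", None)
        cfg = cls(**{k: v for k, v in d.items() if k != "cohort"})
        if cohort is not None:
            import tempfile

            with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
                yaml.safe_dump(cohort, fh)
                tmp = fh.name
            cfg.cohort = CohortConfig.from_yaml(tmp)
            Path(tmp).unlink()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis and write CSV/JSON artifacts to ``out_dir``.

    Returns a dict with the in-memory feature table, association table, site
    screen, per-site classification results and augmentation tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(config.cohort.sites) < 2:
        raise ValueError("classification stage needs at least 2 sites; configure more sites")

    log.info("stage simulate: generating cohort (seed=%d)", config.cohort_seed)
    cohort = generate_cohort(config.cohort, seed=config.cohort_seed)
    if config.write_images:
        write_cohort(cohort, out_dir / "cohort")
    cohort.manifest().to_csv(out_dir / "cohort_manifest.csv", index=False)

    log.info("stage extract: %d tumors", len(cohort.tumors))
    table = build_feature_table(cohort, n_levels=config.n_levels)
    table.to_csv(out_dir / "features.csv", index=False)

    log.info("stage stats: association analysis")
    assoc = association_analysis(table, alpha=config.alpha)
    assoc.table.to_csv(out_dir / "association.csv", index=False)
    screen = anova_site_screen(table, alpha=config.alpha)
    screen.to_csv(out_dir / "site_screen.csv", index=False)

    log.info("stage classify: hold-one-site-out over %d sites", table["site_id"].nunique())
    sets = {k: FEATURE_SETS[k] for k in config.feature_sets}
    results = hold_one_site_out(
        table, feature_sets=sets, seed=config.cv_seed, site_screen=config.site_screen
    )
    perf = results_table(results)
    perf.to_csv(out_dir / "site_results.csv", index=False)
    aug = (
        augmentation_tests(results)
        if {"adc_t2w_hist", "adc_t2w_hist_texture"} <= set(config.feature_sets)
        else {}
    )

    manifest = {
        "config_hash": config.config_hash(),
        "pzrad_version": __version__,
        "cohort_seed": config.cohort_seed,
        "cv_seed": config.cv_seed,
        "n_tumors": len(cohort.tumors),
        "n_patients": int(table["patient_id"].nunique()),
        "class_counts": table["aggressiveness"].value_counts().to_dict(),
        "mean_auc_by_set": perf.groupby("feature_set")["auc"].mean().to_dict(),
        "mean_accuracy_by_set": perf.groupby("feature_set")["accuracy"].mean().to_dict(),
        "augmentation_tests": {
            k: (v if not isinstance(v, dict) else {s: float(x) for s, x in v.items()})
            for k, v in aug.items()
        },
    }
    config.to_yaml(out_dir / "run_config.yaml")
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    return {
        "cohort": cohort,
        "features": table,
        "association": assoc.table,
        "site_screen": screen,
        "results": results,
        "performance": perf,
        "augmentation": aug,
        "manifest": manifest,
    }
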