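"""End-to-end pipeline: curation -> census -> strata -> pairs -> QSAR.

Every output table carries a provenance comment header (package version,
seed, configuration hash) so a run is reproducible from its emitted
configuration and seed alone; no timestamps are written, making reruns
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import CompoundRecord, read_activity_csv
from .curation import BalancedSubsetSelector
from .fingerprints import FingerprintFeaturizer
from .kpls import KernelPLSRegressor, model_rank_score, r2_q2, train_test_split_records
from .stratify import HeteroatomEffectAnalysis
from .synthetic import EffectParams, gen_library

log = logging.getLogger("hergsar")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full analysis run."""

    input: Optional[str] = None          # activity CSV; None -> simulate
    n_simulate: int = 1000
    target_size: int = 508
    bin_width: float = 0.5
    pic50_range: tuple[float, float] = (2.07, 9.85)
    focal_elements: tuple[str, ...] = ("N", "O", "S", "Cl")
    min_size: int = 5
    threshold: float = 0.9
    central: str = "mean"
    mode: str = "total"
    fingerprint: str = "radial"
    kernel: str = "tanimoto"
    ratio: float = 0.85
    n_components: int | str = "auto"
    dedup: str = "median"
    seed: int = 0
    outdir: str = "hergsar_out"

    def __post_init__(self):
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must be in (0, 1)")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.central not in ("mean", "median"):
            raise ValueError("central must be 'mean' or 'median'")
        if self.mode not in ("total", "other"):
            raise ValueError("mode must be 'total' or 'other'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("pic50_range", "focal_elements"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return f"# hergsar {__version__} seed={config.seed} config={config.digest()}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def _load_records(config: PipelineConfig) -> tuple[list[CompoundRecord], pd.DataFrame]:
    if config.input is None:
        records = gen_library(
            config.n_simulate, EffectParams(), seed=config.seed, with_structures=True
        )
        return records, pd.DataFrame(columns=["id", "reason"])
    records, rejects = read_activity_csv(config.input, dedup=config.dedup)
    total = len(records) + len(rejects)
    if total and len(records) / total < 0.5:
        raise ValueError(
            f"more than half of the input failed to parse "
            f"({len(rejects)}/{total} rejected)"
        )
    return records, rejects


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a manifest of written artifacts."""
    records, rejects = _load_records(config)
    if not records:
        raise ValueError("no usable input records")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("input: %d records (%d rejected)", len(records), len(rejects))
    if len(rejects):
        _write_csv(rejects, outdir / "rejects.csv", config)

    # --- curation -------------------------------------------------------
    lo, hi = config.pic50_range
    selector = BalancedSubsetSelector(
        target_size=min(config.target_size, len(records)),
        bin_width=config.bin_width, lo=lo, hi=hi, seed=config.seed,
    )
    subset = selector.fit_select(records)
    log.info("curation: %d -> %d records", len(records), len(subset))
    _write_csv(
        pd.DataFrame(
            {
                "id": [r.id for r in subset],
                "formula": [r.formula for r in subset],
                "smiles": [r.smiles for r in subset],
                "pic50": [r.pic50 for r in subset],
            }
        ),
        outdir / "subset.csv",
        config,
    )
    centers = 0.5 * (selector.bin_edges_[:-1] + selector.bin_edges_[1:])
    _write_csv(
        pd.DataFrame({"bin_center": centers, "quota": selector.quotas_}),
        outdir / "activity_histogram.tsv",
        config,
    )

    # --- strata and effect pairs ---------------------------------------
    analysis = HeteroatomEffectAnalysis(
        focal_elements=config.focal_elements,
        min_size=config.min_size,
        threshold=config.threshold,
        central=config.central,
        mode=config.mode,
    ).fit(subset)

    strata_rows, pair_rows, trend_rows = [], [], []
    for el in config.focal_elements:
        for s in analysis.strata_[el]:
            strata_rows.append(
                {
                    "focal_element": el,
                    "focal_count": s.focal_count,
                    "total_heteroatoms": s.total_heteroatoms,
                    "size": s.size,
                    "median_pic50": round(s.median_pic50, 6),
                    "mean_pic50": round(s.mean_pic50, 6),
                }
            )
        for p in analysis.effect_pairs_[el]:
            pair_rows.append(
                {
                    "focal_element": el,
                    "total_heteroatoms": p.total_heteroatoms,
                    "weak_id": p.weak_compound[0],
                    "weak_pic50": round(p.weak_compound[1], 6),
                    "weak_focal_count": p.weak_stratum.focal_count,
                    "weak_set_central": round(p.weak_stratum.central(config.central), 6),
                    "strong_id": p.strong_compound[0],
                    "strong_pic50": round(p.strong_compound[1], 6),
                    "strong_focal_count": p.strong_stratum.focal_count,
                    "strong_set_central": round(p.strong_stratum.central(config.central), 6),
                    "delta": round(p.delta, 6),
                }
            )
        tr = analysis.trends_[el]
        if tr is not None:
            trend_rows.append(
                {
                    "focal_element": el,
                    "verdict": tr.verdict,
                    "spearman_rho": round(tr.spearman_rho, 6),
                    "turning_point": tr.turning_point,
                    "counts": " ".join(map(str, tr.counts)),
                    "centrals": " ".join(f"{c:.4f}" for c in tr.centrals),
                }
            )
    _write_csv(
        pd.DataFrame(
            strata_rows,
            columns=["focal_element", "focal_count", "total_heteroatoms",
                     "size", "median_pic50", "mean_pic50"],
        ),
        outdir / "strata.csv", config,
    )
    _write_csv(
        pd.DataFrame(
            pair_rows,
            columns=["focal_element", "total_heteroatoms", "weak_id", "weak_pic50",
                     "weak_focal_count", "weak_set_central", "strong_id",
                     "strong_pic50", "strong_focal_count", "strong_set_central",
                     "delta"],
        ),
        outdir / "pairs.csv", config,
    )
    _write_csv(
        pd.DataFrame(
            trend_rows,
            columns=["focal_element", "verdict", "spearman_rho", "turning_point",
                     "counts", "centrals"],
        ),
        outdir / "trends.csv", config,
    )
    log.info(
        "strata: %d; flagged pairs: %d",
        len(strata_rows),
        len(pair_rows),
    )

    # --- QSAR -----------------------------------------------------------
    metrics: dict = {
        "seed": config.seed,
        "config": config.digest(),
        "n_input": len(records),
        "n_subset": len(subset),
        "n_pairs": len(pair_rows),
    }
    with_structure = [r for r in subset if r.mol is not None]
    if len(with_structure) >= 10:
        train, test = train_test_split_records(
            with_structure, ratio=config.ratio, seed=config.seed
        )
        feat = FingerprintFeaturizer(scheme=config.fingerprint)
        fps_train = feat.transform(train)
        fps_test = feat.transform(test)
        model = KernelPLSRegressor(
            n_components=config.n_components, kernel=config.kernel
        ).fit(fps_train, [r.pic50 for r in train])
        pred_test = model.predict(fps_test)
        q2 = r2_q2([r.pic50 for r in test], pred_test, ref_mean=model.y_mean_)
        metrics.update(
            {
                "fingerprint": config.fingerprint,
                "kernel": config.kernel,
                "ratio": config.ratio,
                "n_components": model.n_components_,
                "r2_train": round(model.r2_train_, 6),
                "q2_test": round(q2, 6),
                "rank_score": round(model_rank_score(model.r2_train_, q2), 6),
            }
        )
        pred_train = model.predict(fps_train)
        _write_csv(
            pd.DataFrame(
                {
                    "id": [r.id for r in train] + [r.id for r in test],
                    "set": ["train"] * len(train) + ["test"] * len(test),
                    "observed": [r.pic50 for r in train] + [r.pic50 for r in test],
                    "predicted": np.round(np.concatenate([pred_train, pred_test]), 6),
                }
            ),
            outdir / "predictions.csv",
            config,
        )
        log.info("qsar: R2=%.3f Q2=%.3f", model.r2_train_, q2)
    else:
        log.warning("qsar stage skipped: fewer than 10 records with structures")

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config_resolved.yaml", "w") as fh:
        fh.write(_header(config))
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    manifest = {"outdir": str(outdir), "metrics": metrics}
    return manifest
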