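"""End-to-end pipeline: preprocess → perturb → extract → score → report."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io, robustness, synthdata
from .features import ExtractionConfig, extract_all
from .perturb import make_triplet
from .preprocess import ClaheConfig, clahe
from .types import LesionRecord, PhantomCase

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    ``input_dir`` points at a directory with images, masks and a
    metadata.csv (columns case_id, abnormality, pathology, view, image,
    mask); when it is None a synthetic cohort of ``n_per_stratum`` cases
    per stratum is generated instead.
    """

    input_dir: str | None = None
    n_per_stratum: int = 5
    image_size: tuple[int, int] = (128, 128)
    seed: int = 0
    apply_clahe: bool = True
    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    k: float = 0.06
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    alpha: float = 0.05
    output_dir: str = "radrobust_out"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("perturbation constant k must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        if "clahe" in raw:
            c = raw["clahe"]
            if "tiles" in c and isinstance(c["tiles"], str):
                c["tiles"] = tuple(int(t) for t in c["tiles"].lower().split("x"))
            elif "tiles" in c:
                c["tiles"] = tuple(c["tiles"])
            raw["clahe"] = ClaheConfig(**c)
        if "extraction" in raw:
            raw["extraction"] = ExtractionConfig(**raw["extraction"])
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        return cls(**raw)

    def snapshot(self) -> dict[str, Any]:
        snap = dataclasses.asdict(self)
        return snap


@dataclass
class RunManifest:
    version: str
    config: dict[str, Any]
    case_status: dict[str, str]
    n_feature_rows: int

    @property
    def counts(self) -> dict[str, int]:
        out = {"ok": 0, "degenerate-erosion": 0, "failed": 0}
        for status in self.case_status.values():
            out[status] += 1
        return out


def _load_cases(cfg: RunConfig) -> tuple[list[PhantomCase], dict[str, str]]:
    """Cases plus a status dict for inputs that failed to load (isolated)."""
    if cfg.input_dir is None:
        return synthdata.make_cohort(cfg.n_per_stratum, cfg.image_size, cfg.seed), {}
    indir = Path(cfg.input_dir)
    meta = pd.read_csv(indir / "metadata.csv")
    cases: list[PhantomCase] = []
    failed: dict[str, str] = {}
    for rec in meta.to_dict("records"):
        cid = str(rec["case_id"])
        try:
            image = io.read_image(indir / rec["image"])
            mask = io.read_mask(indir / rec["mask"], image.shape)
            cases.append(
                PhantomCase(
                    image=image,
                    mask=mask,
                    record=LesionRecord(
                        case_id=cid,
                        abnormality=rec["abnormality"],
                        pathology=rec["pathology"],
                        view=rec["view"],
                    ),
                )
            )
        except Exception:
            logger.exception("case %s failed to load; continuing", cid)
            failed[cid] = "failed"
    return cases, failed


def extract_cohort(cases: list[PhantomCase], cfg: RunConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Run preprocess → perturb → extract per case; failures are isolated."""
    rows: list[dict[str, Any]] = []
    status: dict[str, str] = {}
    for case in cases:
        cid = case.record.case_id
        try:
            image = clahe(case.image, cfg.clahe) if cfg.apply_clahe else case.image
            triplet = make_triplet(case.mask, cfg.k)
            rows.extend(extract_all(image, triplet, case.record, cfg.extraction))
            status[cid] = "degenerate-erosion" if triplet.degenerate else "ok"
        except Exception:
            logger.exception("case %s failed; continuing", cid)
            status[cid] = "failed"
    table = io.order_feature_columns(pd.DataFrame(rows))
    return table, status


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the full workflow and write tables, report and manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases, load_failures = _load_cases(cfg)

    table, status = extract_cohort(cases, cfg)
    status.update(load_failures)
    io.write_feature_table(table, outdir / "features.csv")

    reports = []
    for stratum in robustness.default_strata():
        try:
            rep = robustness.score_features(table, stratum, cfg.alpha)
        except ValueError as exc:
            logger.warning("skipping stratum %s: %s", stratum.label(), exc)
            continue
        if not rep.empty:
            reports.append(robustness.assign_levels(rep))
    if reports:
        report = pd.concat(reports, ignore_index=True)
        report.to_csv(outdir / "report.csv", index=False)
        robustness.class_summary(report).to_csv(outdir / "summary.csv", index=False)

    manifest = RunManifest(
        version=__version__,
        config=cfg.snapshot(),
        case_status=status,
        n_feature_rows=len(table),
    )
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "version": manifest.version,
                "config": manifest.config,
                "case_status": manifest.case_status,
                "counts": manifest.counts,
                "n_feature_rows": manifest.n_feature_rows,
            },
            indent=2,
            default=str,
        )
    )
    return manifest
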