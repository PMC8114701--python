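"""End-to-end orchestration: balance -> split -> train -> fuse -> evaluate.

:func:`run_hdeep` runs the full workflow on labeled positive/negative
transcript sets and returns per-sample predictions (Cp_L, Cp_C, fused Cp,
label), metrics for the two base models and the hybrid, and a run manifest
recording the configuration and seeds for reproducibility.  All randomness
funnels through one master seed, expanded deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lncfuse import __version__
from lncfuse.evaluation import confusion, metrics, roc_auc
from lncfuse.hybrid import HybridClassifier, fuse, to_label
from lncfuse.io import DatasetSplit, Transcript, split
from lncfuse.models import BiLstmClassifier, CnnClassifier
from lncfuse.sampling import make_ratio_dataset

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of a full run; model kwargs override estimator defaults."""

    p: int = 3
    split_fraction: float = 0.8
    strategy: str = "lstm"
    ratio: int | None = None  #: 1, 2 or 3 to rebalance negatives; None = as given
    n_clusters: int = 200
    lstm: dict = field(default_factory=dict)
    cnn: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0, **kwargs) -> "PipelineConfig":
        """Desk-scale model sizes for quick runs and tests."""
        return cls(
            lstm=dict(
                embed_dim=24, lstm_units=24, epochs=18, learning_rate=1e-3, clipnorm=5.0
            ),
            cnn=dict(conv_filters=(8, 16), epochs=15, learning_rate=0.02, momentum=0.9),
            seed=seed,
            **kwargs,
        )


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    input_digests: dict
    outputs: list[str]
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


@dataclass
class HdeepResult:
    predictions: pd.DataFrame  #: id, truth, cp_l, cp_c, cp, label per test sample
    metrics: dict  #: per-method metric dicts ("lstm", "cnn", "hybrid")
    model: HybridClassifier
    dataset: DatasetSplit
    manifest: RunManifest


def _digest(transcripts: Sequence[Transcript]) -> str:
    h = hashlib.sha256()
    for t in transcripts:
        h.update(t.seq.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def run_hdeep(
    pos: Sequence[Transcript],
    neg: Sequence[Transcript],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> HdeepResult:
    """Run the hybrid pipeline and evaluate on the held-out test split.

    Stages: optional cluster-undersampling of negatives to the requested
    ratio, stratified 80/20 split, training of the BiLSTM (token view) and
    CNN (one-hot view), decision-level fusion, and evaluation (five
    criteria + AUC per method).
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    pos = list(pos)
    neg = list(neg)
    logger.info("inputs: %d positives, %d negatives", len(pos), len(neg))

    if cfg.ratio is not None:
        pos, neg = make_ratio_dataset(
            pos,
            neg,
            ratio=cfg.ratio,
            n_clusters=cfg.n_clusters,
            seed=derive_seed(cfg.seed, "balance"),
        )
        logger.info("balanced to 1:%d -> %d negatives selected", cfg.ratio, len(neg))

    ds = split(pos + neg, cfg.split_fraction, seed=derive_seed(cfg.seed, "split"))
    logger.info("split: %d train / %d test", len(ds.train), len(ds.test))

    model = HybridClassifier(
        strategy=cfg.strategy,
        lstm=BiLstmClassifier(p=cfg.p, **cfg.lstm),
        cnn=CnnClassifier(**cfg.cnn),
        random_state=derive_seed(cfg.seed, "train"),
    )
    X_train = [t.seq for t in ds.train]
    y_train = np.array([t.label for t in ds.train])
    model.fit(X_train, y_train)

    X_test = [t.seq for t in ds.test]
    y_test = np.array([t.label for t in ds.test])
    cp_l = model.lstm_.predict_cp(X_test)
    cp_c = model.cnn_.predict_cp(X_test)
    cp = fuse(cp_l, cp_c, cfg.strategy)
    labels = to_label(cp)

    predictions = pd.DataFrame(
        {
            "id": [t.id for t in ds.test],
            "truth": y_test,
            "cp_l": cp_l,
            "cp_c": cp_c,
            "cp": cp,
            "label": labels,
        }
    )
    report: dict[str, dict] = {}
    for name, scores in (("lstm", cp_l), ("cnn", cp_c), ("hybrid", cp)):
        rep = metrics(confusion(y_test, to_label(scores)))
        rep.auc = roc_auc(scores, y_test)[0]
        report[name] = rep.as_dict()
    logger.info(
        "test accuracy: lstm %.3f cnn %.3f hybrid %.3f (%.1f s)",
        report["lstm"]["accuracy"],
        report["cnn"]["accuracy"],
        report["hybrid"]["accuracy"],
        time.time() - t0,
    )

    manifest = RunManifest(
        command="hdeep",
        config=asdict(cfg),
        seed=cfg.seed,
        input_digests={"pos": _digest(pos), "neg": _digest(neg)},
        outputs=[],
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    result = HdeepResult(
        predictions=predictions, metrics=report, model=model, dataset=ds, manifest=manifest
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pred_path = outdir / "predictions.tsv"
        metrics_path = outdir / "metrics.json"
        predictions.to_csv(pred_path, sep="\t", index=False)
        metrics_path.write_text(json.dumps(report, indent=2))
        manifest.outputs = [str(pred_path), str(metrics_path)]
        manifest.write(outdir / "manifest.json")
    return result


def ratio_experiment(
    pos: Sequence[Transcript],
    neg: Sequence[Transcript],
    ratios: Sequence[int] = (1, 2, 3),
    config: PipelineConfig | None = None,
) -> dict[int, dict]:
    """Run the pipeline per class ratio; reports F1, AUC and GM for each.

    GM (geometric mean of sensitivity and specificity) is included because
    it remains informative on the imbalanced runs.
    """
    cfg = config or PipelineConfig()
    out: dict[int, dict] = {}
    for r in ratios:
        rcfg = PipelineConfig(**{**asdict(cfg), "ratio": r})
        res = run_hdeep(pos, neg, rcfg)
        hyb = res.metrics["hybrid"]
        out[r] = {"f1": hyb["f1"], "auc": hyb["auc"], "gm": hyb["gm"]}
    return out
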