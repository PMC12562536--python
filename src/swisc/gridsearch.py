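"""Combinatorial model search over feature sets, families, sizes and
sequence lengths, with ranked classification reports.

The default space crosses the four feature sets with the four neural
families, three layer sizes (50, 100, 200) and four sequence lengths
(1, 3, 5, 7) — 192 configurations — plus one linear SVM per feature set,
196 in total. Enumeration order is deterministic: feature set, then family,
then layer size, then sequence length.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from . import metrics
from .errors import ConfigError
from .features import FEATURE_SETS
from .models import ModelConfig, train

NEURAL_FAMILIES = ("dense", "lstm", "bilstm", "stacked_bilstm")


@dataclasses.dataclass
class GridSpace:
    feature_sets: tuple = FEATURE_SETS
    families: tuple = NEURAL_FAMILIES
    layer_sizes: tuple = (50, 100, 200)
    seq_lengths: tuple = (1, 3, 5, 7)
    include_svm: bool = True
    seed: int = 0


def enumerate_grid(space: GridSpace | None = None) -> list[ModelConfig]:
    """All configurations of the space, in deterministic order."""
    space = space or GridSpace()
    for axis in ("feature_sets", "families", "layer_sizes", "seq_lengths"):
        if not getattr(space, axis):
            raise ConfigError(f"grid axis {axis!r} is empty")
    configs: list[ModelConfig] = []
    for fs in space.feature_sets:
        if space.include_svm:
            configs.append(ModelConfig(family="svm", feature_set=fs, seq_len=1,
                                       layer_size=space.layer_sizes[0],
                                       seed=space.seed))
        for fam in space.families:
            for size in space.layer_sizes:
                for seq in space.seq_lengths:
                    configs.append(ModelConfig(family=fam, feature_set=fs,
                                               seq_len=seq, layer_size=size,
                                               seed=space.seed))
    return configs


def _config_tag(cfg: ModelConfig) -> str:
    return f"{cfg.feature_set}-{cfg.family}-L{cfg.layer_size}-S{cfg.seq_len}"


def run_grid(configs, data: dict, budget: int = 20, out_dir=None,
             epochs_per_file: int | None = None) -> list[dict]:
    """Train and evaluate every configuration on validation data.

    ``data`` maps feature-set name -> {"train": (FeatureMatrix, StateLabels),
    "val": (FeatureMatrix, StateLabels)}. ``budget`` caps training epochs for
    the round (20 for the screening pass, 60 for final retraining). Failures
    are recorded per configuration and the grid continues; with ``out_dir``
    each report is streamed to disk and finished configurations are skipped
    on rerun.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: list[dict] = []
    for cfg in configs:
        tag = _config_tag(cfg)
        path = out / f"{tag}.json" if out is not None else None
        if path is not None and path.exists():
            results.append(json.loads(path.read_text()))
            continue
        row: dict = {"config": cfg.to_dict(), "tag": tag, "error": None}
        try:
            if cfg.feature_set not in data:
                raise ConfigError(f"no data prepared for feature set {cfg.feature_set!r}")
            (ftr, ltr) = data[cfg.feature_set]["train"]
            (fva, lva) = data[cfg.feature_set]["val"]
            run_cfg = dataclasses.replace(cfg, max_train_epochs=budget)
            model = train(run_cfg, ftr, ltr, epochs_per_file=epochs_per_file)
            _, pred = model.predict(fva)
            rep = metrics.report(lva, pred)
            row["report"] = rep.to_dict()
            row["f1_weighted"] = rep.f1_weighted
            row["f1_macro"] = rep.f1_macro
        except Exception as e:  # noqa: BLE001 - per-config isolation is the contract
            row["error"] = f"{type(e).__name__}: {e}"
        results.append(row)
        if path is not None:
            path.write_text(json.dumps(row, indent=1))
    return results


def rank_results(results, key: str = "f1_weighted") -> list[dict]:
    """Successful rows sorted by a summary metric, best first."""
    ok = [r for r in results if r.get("error") is None]
    return sorted(ok, key=lambda r: r.get(key, float("-inf")), reverse=True)
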