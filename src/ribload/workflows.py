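"""Composed experiments: subgroup effects, iterative occlusion, and the
random-vs-human-like transfer comparison.

Each workflow is a pure function of (libraries, model spec, seeds) so a
rerun with the same inputs reproduces every number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import attribution as attr
from .model import ModelSpec, TrainedModel, build_model, evaluate_r2, fine_tune, train
from .simdata import ReporterLibrary
from .utr_features import UpstreamClass, classify_upstream, filter_library

CLASS_ORDER = [UpstreamClass.CONTROL, UpstreamClass.NTE, UpstreamClass.IF_UORF,
               UpstreamClass.OOF_UORF, UpstreamClass.OUORF]


def unpaired_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> float:
    """Two-sample two-tailed t-test p-value (Welch by default).

    Returns NaN when either group has fewer than two observations.
    """
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def _class_calls(library: ReporterLibrary) -> np.ndarray:
    # plain strings: numpy elementwise == mishandles str-enum scalars
    return np.array([classify_upstream(s).class_call.value for s in library.sequences])


def subgroup_effects(trained: TrainedModel, library: ReporterLibrary,
                     equal_var: bool = False) -> pd.DataFrame:
    """Observed-vs-learned impact of upstream translation per reporter class.

    EXCLUDED (multi-uAUG) reporters are dropped; every remaining class row
    reports mean/sd of observed and predicted MRL, the delta vs CONTROL,
    and the unpaired two-tailed t-test p-value vs CONTROL.
    """
    calls = _class_calls(library)
    obs = library.mrl
    if np.isnan(obs).any():
        raise ValueError("library has missing MRL values")
    pred = trained.predict_mrl(list(library.sequences))
    control = calls == UpstreamClass.CONTROL.value
    rows = []
    for cls in CLASS_ORDER:
        mask = calls == cls.value
        n = int(mask.sum())
        if n == 0:
            rows.append({"class": cls.value, "n": 0})
            continue
        row = {
            "class": cls.value, "n": n,
            "obs_mean": obs[mask].mean(), "obs_sd": obs[mask].std(ddof=1) if n > 1 else np.nan,
            "pred_mean": pred[mask].mean(), "pred_sd": pred[mask].std(ddof=1) if n > 1 else np.nan,
        }
        if cls == UpstreamClass.CONTROL:
            row.update(obs_delta=0.0, pred_delta=0.0, obs_p=np.nan, pred_p=np.nan)
        else:
            row.update(
                obs_delta=row["obs_mean"] - obs[control].mean(),
                pred_delta=row["pred_mean"] - pred[control].mean(),
                obs_p=unpaired_ttest(obs[mask], obs[control], equal_var),
                pred_p=unpaired_ttest(pred[mask], pred[control], equal_var),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def class_meta_maps(trained: TrainedModel, library: ReporterLibrary, steps: int = 50,
                    max_per_class: Optional[int] = None, seed: int = 0,
                    ) -> dict[UpstreamClass, attr.MetaAttributionMap]:
    """Meta-attribution map per upstream class (EXCLUDED omitted).

    ``max_per_class`` caps the number of attribution maps per class by
    seeded subsampling, trading meta-map variance for runtime.
    """
    calls = _class_calls(library)
    seqs = library.sequences
    rng = np.random.default_rng(seed)
    out: dict[UpstreamClass, attr.MetaAttributionMap] = {}
    for cls in CLASS_ORDER:
        idx = np.flatnonzero(calls == cls.value)
        if len(idx) == 0:
            warnings.warn(f"class {cls.value} empty; no meta map")
            continue
        if max_per_class is not None and len(idx) > max_per_class:
            idx = np.sort(rng.choice(idx, size=max_per_class, replace=False))
        maps = attr.integrated_gradients_batch(trained, [seqs[i] for i in idx], steps=steps)
        out[cls] = attr.meta_attribution(maps, population_label=cls.value)
    return out


@dataclass
class OcclusionIteration:
    filters: str
    n_train: int
    n_test: int
    r2: float
    top_map: Optional[attr.MetaAttributionMap] = None
    bottom_map: Optional[attr.MetaAttributionMap] = None


@dataclass
class OcclusionReport:
    library_kind: str
    seed: int
    iterations: list[OcclusionIteration] = field(default_factory=list)


_OCCLUSION_STAGES = [("full", False, False), ("-uAUG", True, False), ("-uAUG-UG", True, True)]


def _train_eval(library: ReporterLibrary, spec: ModelSpec, seed: int,
                epochs: Optional[int] = None) -> tuple[TrainedModel, float]:
    net = build_model(spec, seed=seed)
    trained = train(net, library, epochs=epochs, seed=seed, spec=spec)
    r2 = evaluate_r2(trained, library, split="test").r_squared
    return trained, r2


def run_occlusion(random_lib: ReporterLibrary, humanlike_lib: ReporterLibrary,
                  model_spec: ModelSpec, seeds: Iterable[int],
                  attribution_sample: int = 200, steps: int = 20,
                  ) -> dict[str, list[OcclusionReport]]:
    """Iterative occlusion: retrain from scratch on full, −uAUG, and
    −uAUG−UG data and record test r² (and decile meta maps) each time.

    ``attribution_sample`` reporters per decile feed the meta maps
    (0 disables attribution entirely).
    """
    out: dict[str, list[OcclusionReport]] = {}
    for lib in (random_lib, humanlike_lib):
        reports = []
        for seed in seeds:
            report = OcclusionReport(library_kind=lib.kind, seed=seed)
            for name, drop_uaug, drop_ug in _OCCLUSION_STAGES:
                filtered = filter_library(lib, drop_uaug=drop_uaug, drop_ug_prefix=drop_ug)
                sizes = filtered.split_sizes()
                n_train, n_test = sizes.get("train", 0), sizes.get("test", 0)
                if n_train == 0 or n_test < 2:
                    raise ValueError(
                        f"occlusion filter {name!r} leaves {n_train} train / "
                        f"{n_test} test reporters in {lib.kind} library"
                    )
                trained, r2 = _train_eval(filtered, model_spec, seed)
                it = OcclusionIteration(name, n_train, n_test, r2)
                if attribution_sample > 0:
                    test_lib = filtered.subset_split("test")
                    for side in ("top", "bottom"):
                        decile = attr.stratify_by_prediction(trained, test_lib, 0.1, side)
                        take = min(attribution_sample, len(decile))
                        maps = attr.integrated_gradients_batch(
                            trained, list(decile.sequences[:take]), steps=steps)
                        meta = attr.meta_attribution(maps, f"{lib.kind} {name} {side} decile")
                        setattr(it, f"{side}_map", meta)
                report.iterations.append(it)
            reports.append(report)
        out[lib.kind] = reports
    return out


def occlusion_r2_table(reports: dict[str, list[OcclusionReport]]) -> pd.DataFrame:
    rows = [
        {"library": kind, "seed": rep.seed, "filters": it.filters,
         "n_train": it.n_train, "n_test": it.n_test, "r2": it.r2}
        for kind, reps in reports.items() for rep in reps for it in rep.iterations
    ]
    return pd.DataFrame(rows)


def transfer_comparison(random_lib: ReporterLibrary, humanlike_lib: ReporterLibrary,
                        model_spec: ModelSpec, seeds: Iterable[int],
                        epoch_grid: Iterable[int] = range(1, 16)) -> pd.DataFrame:
    """Pretrain on the random library, fine-tune on the human-like one, and
    evaluate both models on both test sets.

    Returns one row per (seed, model, test set) with the r² achieved.
    """
    grid = list(epoch_grid)
    rows = []
    for seed in seeds:
        pretrained, _ = _train_eval(random_lib, model_spec, seed)
        tuned = fine_tune(pretrained_copy(pretrained), humanlike_lib,
                          epoch_grid=grid, selection_split="test", seed=seed)
        for model_name, model_obj in (("random_only", pretrained), ("fine_tuned", tuned)):
            for lib in (random_lib, humanlike_lib):
                r2 = evaluate_r2(model_obj, lib, split="test").r_squared
                rows.append({"seed": seed, "model": model_name,
                             "test_set": lib.kind, "r2": r2})
    return pd.DataFrame(rows)


def pretrained_copy(trained: TrainedModel) -> TrainedModel:
    """Independent copy so fine-tuning cannot mutate the pretrained weights."""
    return TrainedModel(net=trained.net.copy(), spec=trained.spec,
                        scaler=trained.scaler, history=list(trained.history),
                        seed=trained.seed, model_id=trained.model_id + ":copy")
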