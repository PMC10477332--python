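"""End-to-end orchestration with a leak-free outer evaluation harness.

The full method is: extract features -> MIC prefilter -> QPSO wrapper.
Performance is estimated with outer stratified k-fold cross-validation
(default 5 folds): in each fold both selection stages are fit on the
training portion only, and the selected mask + SVM parameters are then
scored once on the held-out fold. The per-fold dimension-reduction rate and
validation accuracy are combined into the dimension-aware weighted score.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import FeatureMatrix
from .filter_stage import mic_prefilter
from .wrapper_stage import FitnessConfig, phi_weight, select


@dataclass
class PipelineConfig:
    """All stage parameters plus the outer-harness settings."""

    run_prefilter: bool = True
    run_wrapper: bool = True
    t_irr: float = 0.2
    t_red: float = 0.8
    n_particles: int = 200
    t_max: int = 200
    k_folds: int = 3
    outer_folds: int = 5
    seed: int = 0
    d_original: int | None = None
    svm_bounds: tuple[float, float, float, float] = (0.01, 100.0, 0.01, 100.0)
    log_scale: bool = False
    #: re-fit the prefilter inside every outer fold (leak-free). Set False
    #: for the fit-once-on-all-data compatibility behaviour.
    prefilter_per_fold: bool = True

    def __post_init__(self) -> None:
        if not (self.run_prefilter or self.run_wrapper):
            raise ValueError("at least one stage must be enabled")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")


@dataclass
class Report:
    """Per-fold results plus their arithmetic means."""

    folds: list[dict]
    means: dict
    d_original: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"d_original": self.d_original,
                           "config": self.config,
                           "folds": self.folds,
                           "means": self.means},
                          indent=2, sort_keys=True)


def weighted_score(CA: float, DR: float, d: int) -> float:
    """Dimension-aware combination ``phi(d) * CA + (1 - phi(d)) * DR``."""
    if not 0.0 <= CA <= 1.0:
        raise ValueError("CA must lie in [0, 1]")
    if not 0.0 <= DR <= 1.0:
        raise ValueError("DR must lie in [0, 1]")
    phi = phi_weight(d)
    return phi * CA + (1.0 - phi) * DR


def _validation_accuracy(F: FeatureMatrix, train: np.ndarray,
                         test: np.ndarray, cols: list[int],
                         C: float, gamma: float) -> float:
    X_tr = F.values[np.ix_(train, cols)]
    X_te = F.values[np.ix_(test, cols)]
    scaler = StandardScaler().fit(X_tr)
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(scaler.transform(X_tr), F.labels[train])
    return float(clf.score(scaler.transform(X_te), F.labels[test]))


def run_pipeline(F: FeatureMatrix, config: PipelineConfig | None = None
                 ) -> Report:
    """Run the enabled stages under the outer cross-validation harness."""
    config = config or PipelineConfig()
    d = config.d_original if config.d_original is not None else F.n_features

    global_prefilter = None
    if config.run_prefilter and not config.prefilter_per_fold:
        global_prefilter = mic_prefilter(F, config.t_irr, config.t_red)

    skf = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                          random_state=config.seed)
    folds: list[dict] = []
    for fold, (train, test) in enumerate(skf.split(F.values, F.labels)):
        F_tr = F.subset(rows=train)
        entry: dict = {"fold": fold, "n_train": int(train.size),
                       "n_validation": int(test.size)}

        if config.run_prefilter:
            pre = (global_prefilter if global_prefilter is not None
                   else mic_prefilter(F_tr, config.t_irr, config.t_red))
            kept = list(pre.kept)
            entry["prefilter"] = pre.to_dict()
        else:
            kept = list(range(F.n_features))
        entry["n_candidates"] = len(kept)

        if config.run_wrapper:
            fold_seed = int((config.seed * 1000 + fold) % (2 ** 31))
            fit_cfg = FitnessConfig(d_original=d, k_folds=config.k_folds,
                                    svm_bounds=config.svm_bounds,
                                    log_scale=config.log_scale,
                                    cv_seed=fold_seed)
            sel = select(F_tr.subset(cols=np.array(kept)), fit_cfg,
                         n_particles=config.n_particles,
                         t_max=config.t_max, seed=fold_seed)
            selected = [kept[i] for i in np.flatnonzero(sel.mask)]
            if selected:
                ca = _validation_accuracy(F, train, test, selected,
                                          sel.svm.C, sel.svm.gamma)
            else:
                ca = 0.0
            dr = 1.0 - len(selected) / d
            entry.update({
                "selected": selected,
                "selected_names": [F.names[i] for i in selected],
                "n_selected": len(selected),
                "svm": {"C": sel.svm.C, "sigma": sel.svm.sigma},
                "inner_fitness": sel.fitness,
                "validation_ca": ca,
                "dr": dr,
                "weighted": weighted_score(ca, dr, d),
            })
        folds.append(entry)

    means: dict = {}
    if config.run_wrapper:
        for key in ("validation_ca", "dr", "weighted", "n_selected"):
            means[f"mean_{key}"] = float(np.mean([f[key] for f in folds]))
    means["mean_n_candidates"] = float(np.mean([f["n_candidates"]
                                                for f in folds]))

    cfg_echo = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()}
    return Report(folds=folds, means=means, d_original=d, config=cfg_echo)
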