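"""Brand-held-out validation design and split-half cross-validation.

Validation mirrors the study's robustness design: each of six schemes holds
out every mixture prepared with one brand (schemes 1-3 hold out gin brands
G3, G2, G1; schemes 4-6 tonic brands T3, T2, T1) as a test set. Model
selection — pre-treatment and number of latent variables — runs entirely
inside each scheme's training block as a split-half cross-validation whose
two cancelation groups are the two remaining brands of the held-out type,
so no brand ever informs predictions about itself and pipeline statistics
never leak across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .plsda import encode_classes, lda_threshold
from .pls import fit_pls
from .preprocess import CANDIDATE_PIPELINES, PreprocessingPipeline
from .spectra import SpectraSet

__all__ = ["SplitScheme", "CVResult", "brand_holdout_splits", "split_half_cv",
           "select_model"]

Combo = tuple[str, str]


@dataclass(frozen=True)
class SplitScheme:
    """One train/test split with its two CV cancelation groups.

    ``test_combos`` are the 3 gin x tonic pairs of the held-out brand;
    ``train_combos`` the remaining 6; ``cv_groups`` partitions the training
    combos into the two remaining brands' blocks.
    """

    scheme_id: int
    held_out: str
    test_combos: tuple[Combo, ...]
    train_combos: tuple[Combo, ...]
    cv_groups: tuple[tuple[Combo, ...], tuple[Combo, ...]]

    def __post_init__(self) -> None:
        test, train = set(self.test_combos), set(self.train_combos)
        if test & train:
            raise ParameterError("test and train combos overlap")
        a, b = (set(g) for g in self.cv_groups)
        if len(self.cv_groups[0]) != 3 or len(self.cv_groups[1]) != 3:
            raise ParameterError("each cancelation group must hold 3 combos")
        if (a | b) != train or (a & b):
            raise ParameterError("cancelation groups must partition the training combos")

    @property
    def test_label(self) -> str:
        return "".join(g + t for g, t in self.test_combos)


def brand_holdout_splits(dataset: SpectraSet) -> list[SplitScheme]:
    """The six brand-held-out schemes for a full 3 gin x 3 tonic design.

    Scheme order matches the held-out-brand order of the report tables:
    1-3 leave out gins G3, G2, G1; 4-6 leave out tonics T3, T2, T1.
    """
    gins = sorted(set(dataset.gin_brand))
    tonics = sorted(set(dataset.tonic_brand))
    if len(gins) != 3 or len(tonics) != 3:
        raise DegenerateInputError(
            f"need 3 gin and 3 tonic brands, found {len(gins)} x {len(tonics)}"
        )
    present = set(dataset.combination)
    missing = [g + t for g in gins for t in tonics if g + t not in present]
    if missing:
        raise DegenerateInputError(f"design is missing combinations: {missing}")

    schemes: list[SplitScheme] = []
    for i, g_out in enumerate(reversed(gins), start=1):
        g_in = [g for g in gins if g != g_out]
        schemes.append(SplitScheme(
            scheme_id=i,
            held_out=g_out,
            test_combos=tuple((g_out, t) for t in tonics),
            train_combos=tuple((g, t) for g in g_in for t in tonics),
            cv_groups=(tuple((g_in[0], t) for t in tonics),
                       tuple((g_in[1], t) for t in tonics)),
        ))
    for i, t_out in enumerate(reversed(tonics), start=4):
        t_in = [t for t in tonics if t != t_out]
        schemes.append(SplitScheme(
            scheme_id=i,
            held_out=t_out,
            test_combos=tuple((g, t_out) for g in gins),
            train_combos=tuple((g, t) for t in t_in for g in gins),
            cv_groups=(tuple((g, t_in[0]) for g in gins),
                       tuple((g, t_in[1]) for g in gins)),
        ))
    return schemes


@dataclass
class CVResult:
    """Cross-validated error grid over (pre-treatment, latent variables)."""

    task: str
    candidates: tuple[str, ...]
    F_grid: tuple[int, ...]
    errors: dict[tuple[str, int], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pre_treatment": label, "lvs": F, "cv_error": self.errors[(label, F)]}
            for label in self.candidates
            for F in self.F_grid
        ]
        return pd.DataFrame(rows)

    @property
    def chosen(self) -> tuple[str, int]:
        return select_model(self)


def split_half_cv(
    train: SpectraSet,
    scheme: SplitScheme,
    candidates: tuple[str, ...] = CANDIDATE_PIPELINES,
    F_max: int = 25,
    task: str = "da",
    priors: str = "equal",
    sg_window: int | None = None,
    sg_polyorder: int | None = None,
) -> CVResult:
    """Two-fold CV over the scheme's brand cancelation groups.

    For every candidate pre-treatment and every model size 1..F_max the model
    is fitted on one cancelation group (pipeline state fitted on that group
    alone), evaluated on the other, and vice versa; errors are pooled over
    both folds. ``task="da"`` pools the misclassification rate (with the LDA
    threshold re-derived inside each fold); ``task="reg"`` pools squared
    concentration errors into an RMSECV.
    """
    if task not in ("da", "reg"):
        raise ParameterError(f"task must be 'da' or 'reg', got {task!r}")
    folds = [train.subset_by_combination(g) for g in scheme.cv_groups]
    if any(f.n_samples == 0 for f in folds):
        raise DegenerateInputError("both cancelation groups must be nonempty")

    n_total = sum(f.n_samples for f in folds)
    F_cap = min(f.n_samples - 1 for f in folds)
    F_eff = min(F_max, F_cap)
    if F_eff < F_max:
        warnings.warn(
            f"F_max={F_max} exceeds the fold rank; clipped to {F_eff}", stacklevel=2
        )

    per_label: dict[str, np.ndarray] = {}
    for label in candidates:
        F_lab = F_eff  # may shrink if a pre-treatment drops wavenumbers below F
        pooled = np.zeros(F_eff)  # misclassification counts or SSE per F
        for fit_set, eval_set in ((folds[0], folds[1]), (folds[1], folds[0])):
            pipe = PreprocessingPipeline(label, sg_window=sg_window,
                                         sg_polyorder=sg_polyorder)
            X_fit = pipe.fit_transform(fit_set.absorbance, fit_set.wavenumbers,
                                       fit_set.sample_ids)
            X_eval = pipe.transform(eval_set.absorbance, eval_set.wavenumbers,
                                    eval_set.sample_ids)
            if task == "reg":
                y_fit = fit_set.concentration
                y_eval = eval_set.concentration
            else:
                y_fit = encode_classes(fit_set.class_label)
                y_eval = encode_classes(eval_set.class_label)
            F_lab = min(F_lab, X_fit.shape[1])
            model = fit_pls(X_fit, y_fit, F_lab, strict_rank=False)
            F_lab = min(F_lab, model.F)
            pred_eval = model.predict_all_components(X_eval)
            if task == "reg":
                pooled[:F_lab] += np.sum(
                    (pred_eval[:, :F_lab] - y_eval[:, None]) ** 2, axis=0)
            else:
                pred_fit = model.predict_all_components(X_fit)
                for f in range(F_lab):
                    thr = lda_threshold(pred_fit[:, f], y_fit, priors=priors)
                    called_spiked = pred_eval[:, f] > thr.threshold
                    pooled[f] += np.sum(called_spiked != (y_eval == 1.0))
        per_label[label] = pooled[:F_lab]

    F_common = min(len(v) for v in per_label.values())
    errors: dict[tuple[str, int], float] = {}
    for label, pooled in per_label.items():
        for f in range(F_common):
            err = (np.sqrt(pooled[f] / n_total) if task == "reg"
                   else pooled[f] / n_total)
            errors[(label, f + 1)] = float(err)

    return CVResult(task=task, candidates=tuple(candidates),
                    F_grid=tuple(range(1, F_common + 1)), errors=errors)


def select_model(cv: CVResult) -> tuple[str, int]:
    """Global minimizer of the CV grid; ties break to fewer latent variables,
    then to candidate order."""
    if not cv.errors:
        raise DegenerateInputError("empty CV grid")
    order = {label: i for i, label in enumerate(cv.candidates)}
    return min(cv.errors,
               key=lambda k: (cv.errors[k], k[1], order[k[0]]))
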