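"""Stage 2 — stepwise feature selection, LDA, and cross-validation fusion.

The 128 perceptive features of each lesion *view* are the classifier
inputs; training is lesion-wise (CC and MLO views are undifferentiated
samples), while evaluation is case-wise: the view probabilities of a case
are averaged into one probability of malignancy (POM).

Feature selection is classical forward/backward stepwise regression on an
ordinary linear model of the 0/1 label: a candidate enters when its
partial-F p-value falls below ``p_enter`` (default 0.05) and a selected
variable leaves when its p-value rises above ``p_remove`` (default 0.10) —
the stepwisefit defaults.  The classifier is equal-covariance Gaussian
discriminant analysis (LDA) whose malignant-class posterior is the POM;
the pooled covariance is ridged by ``eps * trace/d`` when singular.

An ensemble is built by K-fold cross-validation at case level (default
K=10; both views of a case always share a fold): each member trains its
own feature extractor and (selector, LDA) pair on the K-1 training folds.
At test time the member POMs of a case are averaged into the fused POM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .extractor import (
    ExtractorConfig,
    TrainedExtractor,
    extract_batch,
    train as train_extractor,
)
from .phantom import Case, LesionPatch

__all__ = [
    "SelectionResult",
    "LdaModel",
    "MemberModel",
    "EnsembleModel",
    "PomScore",
    "stepwise_select",
    "fit_lda",
    "score_lesion",
    "case_pom",
    "assign_folds",
    "crossval_train",
    "oof_poms",
    "fused_pom",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of stepwise selection: chosen feature indices plus the move trace.

    ``trace`` records every move as (step, "enter"/"remove", index, p_value);
    replaying it reproduces ``selected_indices``.
    """

    selected_indices: tuple[int, ...]
    trace: tuple[tuple[int, str, int, float], ...]
    p_enter: float
    p_remove: float

    def __post_init__(self) -> None:
        idx = self.selected_indices
        if list(idx) != sorted(set(idx)):
            raise ValueError("selected_indices must be unique and sorted")


@dataclass
class LdaModel:
    """Equal-covariance Gaussian discriminant (class 1 = malignant).

    POM is the Gaussian posterior of the malignant class under the pooled
    covariance and the stored priors.
    """

    means: np.ndarray  # (2, d)
    pooled_cov: np.ndarray  # (d, d)
    priors: np.ndarray  # (2,)
    #: cached coefficients of the linear discriminant: pom = sigmoid(x.w + b)
    coef: np.ndarray = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if not np.allclose(self.pooled_cov, self.pooled_cov.T):
            raise ValueError("pooled covariance must be symmetric")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        # log-posterior odds of class 1 vs 0 are linear in x
        prec = np.linalg.pinv(self.pooled_cov)
        d_mean = self.means[1] - self.means[0]
        self.coef = prec @ d_mean
        self.intercept = float(
            -0.5 * (self.means[1] @ prec @ self.means[1] - self.means[0] @ prec @ self.means[0])
            + np.log(self.priors[1] / self.priors[0])
        )

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """P(malignant | x) for rows of x (n x d)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        from scipy.special import expit

        return expit(x @ self.coef + self.intercept)

    def discriminant(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return x @ self.coef + self.intercept


@dataclass(frozen=True)
class PomScore:
    """Case-level probability of malignancy."""

    case_id: str
    pom: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pom <= 1.0:
            raise ValueError(f"POM {self.pom} outside [0, 1]")


# ---------------------------------------------------------------------------
# stepwise regression selection
# ---------------------------------------------------------------------------


def _partial_f_pvalues(
    x: np.ndarray, y: np.ndarray, selected: list[int], candidates: Sequence[int]
) -> dict[int, float]:
    """p-value of the partial F-test for adding each candidate to the model."""
    n = len(y)
    base = np.column_stack([np.ones(n)] + [x[:, j] for j in selected])
    beta0, *_ = np.linalg.lstsq(base, y, rcond=None)
    rss0 = float(((y - base @ beta0) ** 2).sum())
    out = {}
    for j in candidates:
        design = np.column_stack([base, x[:, j]])
        k = design.shape[1]
        if n <= k:
            continue
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss1 = float(((y - design @ beta) ** 2).sum())
        df2 = n - k
        if rss1 <= 0:
            out[j] = 0.0
            continue
        f = max(rss0 - rss1, 0.0) / (rss1 / df2)
        out[j] = float(stats.f.sf(f, 1, df2))
    return out


def _removal_pvalues(x: np.ndarray, y: np.ndarray, selected: list[int]) -> dict[int, float]:
    """p-value of each selected variable's partial F given the others."""
    out = {}
    for j in selected:
        others = [k for k in selected if k != j]
        out[j] = _partial_f_pvalues(x, y, others, [j])[j]
    return out


def stepwise_select(
    features: np.ndarray,
    labels: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> SelectionResult:
    """Forward/backward stepwise regression of the 0/1 label on features.

    A variable enters when its partial-F p-value is below ``p_enter``,
    leaves when above ``p_remove``; ties break on lowest p-value then
    lowest index; terminates when no move is possible.  Constant columns
    are never selectable.  Deterministic given inputs.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be n x p with one label per row")
    n, p = x.shape
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")
    if n < 3:
        raise ValueError(f"too few samples (n={n}) for stepwise selection")
    eligible = [j for j in range(p) if np.ptp(x[:, j]) > 0]

    selected: list[int] = []
    trace: list[tuple[int, str, int, float]] = []
    seen: set[tuple[int, ...]] = set()
    for step in range(max_steps):
        moved = False
        # forward
        cands = [j for j in eligible if j not in selected]
        if cands and len(selected) + 2 < n:
            pvals = _partial_f_pvalues(x, y, selected, cands)
            if pvals:
                j_best = min(pvals, key=lambda j: (pvals[j], j))
                if pvals[j_best] < p_enter:
                    selected.append(j_best)
                    trace.append((step, "enter", j_best, pvals[j_best]))
                    moved = True
        # backward
        if selected:
            pvals = _removal_pvalues(x, y, selected)
            j_worst = max(selected, key=lambda j: (pvals[j], -j))
            if pvals[j_worst] > p_remove:
                selected.remove(j_worst)
                trace.append((step, "remove", j_worst, pvals[j_worst]))
                moved = True
        key = tuple(sorted(selected))
        if not moved or key in seen:
            break
        seen.add(key)
    return SelectionResult(
        selected_indices=tuple(sorted(selected)),
        trace=tuple(trace),
        p_enter=p_enter,
        p_remove=p_remove,
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

_COV_EPS = 1e-6


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
) -> LdaModel:
    """Fit the equal-covariance Gaussian discriminant on view-level samples.

    ``labels`` are 0 (benign) / 1 (malignant); priors default to empirical
    class frequencies.  A singular pooled covariance is regularized by
    adding ``1e-6 * trace/d`` to the diagonal.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"both classes must be present, got labels {classes}")
    n, d = x.shape
    means = np.stack([x[y == c].mean(axis=0) for c in (0, 1)])
    resid = x - means[y]
    pooled = resid.T @ resid / max(n - 2, 1)
    pooled = (pooled + pooled.T) / 2
    if np.linalg.matrix_rank(pooled) < d or np.linalg.cond(pooled) > 1e12:
        pooled = pooled + np.eye(d) * (_COV_EPS * np.trace(pooled) / d + 1e-12)
    if priors is None:
        priors = np.array([(y == 0).mean(), (y == 1).mean()])
    return LdaModel(means=means, pooled_cov=pooled, priors=np.asarray(priors, dtype=np.float64))


# ---------------------------------------------------------------------------
# member models, ensembles, fusion
# ---------------------------------------------------------------------------


@dataclass
class MemberModel:
    """One cross-validation member: extractor + feature subset + LDA."""

    extractor: TrainedExtractor
    selection: SelectionResult
    lda: LdaModel

    def validate(self) -> None:
        if self.lda.d != len(self.selection.selected_indices):
            raise ValueError(
                f"LDA dimension {self.lda.d} != selected feature count "
                f"{len(self.selection.selected_indices)}"
            )


@dataclass
class EnsembleModel:
    """K member models plus the case-to-fold assignment that produced them."""

    members: list[MemberModel]
    fold_of_case: dict[str, int]
    k: int

    def validate(self) -> None:
        if len(self.members) != self.k:
            raise ValueError(f"expected {self.k} members, got {len(self.members)}")
        folds = set(self.fold_of_case.values())
        if folds - set(range(self.k)):
            raise ValueError("fold indices out of range")


def score_lesion(model: MemberModel, patch: LesionPatch) -> float:
    """View-level POM: extract features, subset, LDA malignant posterior."""
    model.validate()
    feats = extract_batch(model.extractor, [patch])[0]
    sub = feats[list(model.selection.selected_indices)]
    return float(model.lda.posterior(sub[None])[0])


def case_pom(view_poms: Sequence[float], case_id: str = "") -> PomScore:
    """Arithmetic mean of the available view POMs."""
    if len(view_poms) == 0:
        raise ValueError("case has no view POMs")
    return PomScore(case_id=case_id, pom=float(np.mean(view_poms)))


def _member_case_pom(model: MemberModel, case: Case) -> PomScore:
    model.validate()
    views = sorted(case.patches)
    feats = extract_batch(model.extractor, [case.patches[v] for v in views])
    sub = feats[:, list(model.selection.selected_indices)]
    poms = model.lda.posterior(sub)
    return case_pom(list(poms), case_id=case.case_id)


def assign_folds(
    cases: Sequence[Case], k: int, seed: int, stratify: bool = True
) -> dict[str, int]:
    """Randomly partition cases into K folds at case level.

    Stratified by pathology label by default so each fold keeps the class
    mix; fold sizes differ by at most one.
    """
    n = len(cases)
    if k < 2:
        raise ValueError("K must be >= 2")
    if k > n:
        raise ValueError(f"K={k} exceeds {n} cases")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))
    fold_of_case: dict[str, int] = {}
    if stratify:
        groups = [
            [c.case_id for c in cases if c.label == lab] for lab in ("benign", "malignant")
        ]
    else:
        groups = [[c.case_id for c in cases]]
    next_fold = rng.integers(k)  # stagger so small strata spread evenly
    for ids in groups:
        ids = rng.permutation(ids)
        for cid in ids:
            fold_of_case[cid] = int(next_fold)
            next_fold = (next_fold + 1) % k
    return fold_of_case


def train_member(
    cases: Sequence[Case],
    extractor_config: ExtractorConfig,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    val_cases: Sequence[Case] | None = None,
) -> MemberModel:
    """Train Stage 1 then Stage 2 on one training split (lesion-wise)."""
    extractor = train_extractor(cases, extractor_config, val_cases=val_cases)
    extractor.freeze()
    patches = [case.patches[v] for case in cases for v in sorted(case.patches)]
    labels = np.array(
        [1 if case.label == "malignant" else 0 for case in cases for _ in (0, 1)]
    )
    feats = extract_batch(extractor, patches)
    selection = stepwise_select(feats, labels, p_enter=p_enter, p_remove=p_remove)
    if not selection.selected_indices:
        # degenerate stepwise outcome: fall back to the single best feature
        pvals = _partial_f_pvalues(feats, labels.astype(float), [], list(range(feats.shape[1])))
        j = min(pvals, key=lambda j: (pvals[j], j))
        selection = SelectionResult((j,), ((0, "enter", j, pvals[j]),), p_enter, p_remove)
    lda = fit_lda(feats[:, list(selection.selected_indices)], labels)
    member = MemberModel(extractor=extractor, selection=selection, lda=lda)
    member.validate()
    return member


def crossval_train(
    cases: Sequence[Case],
    k: int = 10,
    extractor_config: ExtractorConfig | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    seed: int = 0,
    stratify: bool = True,
    monitor_validation: bool = False,
    progress: Callable[[str], None] | None = None,
) -> EnsembleModel:
    """K-fold cross-validation training (default K=10).

    Cases are partitioned at case level (views never split across folds);
    each member trains Stage 1 and Stage 2 on its K-1 training folds.  Each
    member's extractor seed is derived from ``seed`` and the fold index.
    """
    if extractor_config is None:
        extractor_config = ExtractorConfig()
    fold_of_case = assign_folds(cases, k, seed, stratify=stratify)
    members = []
    for fold in range(k):
        train_cases = [c for c in cases if fold_of_case[c.case_id] != fold]
        val_cases = [c for c in cases if fold_of_case[c.case_id] == fold]
        if progress:
            progress(f"fold {fold + 1}/{k}: {len(train_cases)} train cases")
        cfg = dc_replace(
            extractor_config,
            seed=int(np.random.SeedSequence((seed, fold)).generate_state(1)[0] % 2**31),
        )
        use_val = monitor_validation or cfg.freeze_policy == "best_val"
        members.append(
            train_member(
                train_cases,
                cfg,
                p_enter=p_enter,
                p_remove=p_remove,
                val_cases=val_cases if use_val else None,
            )
        )
    ensemble = EnsembleModel(members=members, fold_of_case=fold_of_case, k=k)
    ensemble.validate()
    return ensemble


def oof_poms(ensemble: EnsembleModel, cases: Sequence[Case]) -> dict[str, PomScore]:
    """Out-of-fold POMs: each case is scored by its own fold's member.

    The member of a case's validation fold never saw that case during
    training, so these scores are the cross-validated ("held-out")
    predictions over the training collection.
    """
    out: dict[str, PomScore] = {}
    for case in cases:
        if case.case_id not in ensemble.fold_of_case:
            raise KeyError(f"case {case.case_id} has no fold assignment in this ensemble")
        member = ensemble.members[ensemble.fold_of_case[case.case_id]]
        out[case.case_id] = _member_case_pom(member, case)
    return out


def fused_pom(ensemble: EnsembleModel, case: Case) -> PomScore:
    """Mean over the K members of the case-level POM."""
    poms = []
    for i, member in enumerate(ensemble.members):
        try:
            poms.append(_member_case_pom(member, case).pom)
        except Exception as exc:  # noqa: BLE001 - contract: name the failing member
            raise RuntimeError(f"ensemble member {i} failed on case {case.case_id}") from exc
    return PomScore(case_id=case.case_id, pom=float(np.mean(poms)))
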