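"""Per-donor stepwise regression of activation on two genes + interaction.

Does the focal gene carry signal beyond a known co-regressor?  Within each
donor, activation likelihood at the sampling sites is regressed on the two
standardized gene expressions and their elementwise product, selected by
bidirectional stepwise on partial t-test p-values (enter at p < p_enter,
remove at p > p_remove).  Terms a donor does not select get a beta of
exactly zero, and the per-term beta vectors are pooled across donors with
the same one-sample t-test as the main analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .similarity import RandomEffectsResult, _one_sample_t

__all__ = [
    "StepwiseFit",
    "interaction_term",
    "stepwise_fit",
    "random_effects_on_betas",
]

P_ENTER_DEFAULT = 0.05
P_REMOVE_DEFAULT = 0.10
_COND_LIMIT = 1e8


@dataclass
class StepwiseFit:
    donor_id: str
    candidates: tuple[str, ...]
    selected: tuple[str, ...]
    betas: dict[str, float]  # standardized; unselected terms exactly 0
    adj_r2: float
    model_p: float


def interaction_term(g1_std: np.ndarray, g2_std: np.ndarray) -> np.ndarray:
    """Elementwise product of two standardized expression vectors."""
    g1 = np.asarray(g1_std, dtype=float).ravel()
    g2 = np.asarray(g2_std, dtype=float).ravel()
    if g1.size != g2.size:
        raise ValueError("interaction inputs must have equal length")
    for name, g in (("g1", g1), ("g2", g2)):
        if abs(g.mean()) > 1e-6 or abs(g.std(ddof=1) - 1.0) > 1e-3:
            raise ValueError(
                f"{name} is not standardized (mean {g.mean():.2e}, "
                f"sd {g.std(ddof=1):.4f})"
            )
    return g1 * g2


def _check_collinear(candidates: dict[str, np.ndarray]) -> None:
    names = list(candidates)
    X = np.column_stack([candidates[n] for n in names])
    if len(names) >= 2:
        c = np.corrcoef(X, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(c[i, j]) > 0.9999:
                    raise ValueError(
                        f"collinear candidates: {names[i]!r} and {names[j]!r}"
                    )
    if np.linalg.cond(np.column_stack([np.ones(X.shape[0]), X])) > _COND_LIMIT:
        raise ValueError("candidate design matrix is ill-conditioned")


def _fit_ols(y: np.ndarray, cols: list[np.ndarray]):
    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((y.size, 1))
    return sm.OLS(y, X).fit()


def _term_pvalues(y, candidates, selected) -> dict[str, float]:
    res = _fit_ols(y, [candidates[n] for n in selected])
    return {n: float(res.pvalues[i + 1]) for i, n in enumerate(selected)}


def stepwise_fit(
    y: np.ndarray,
    candidates: dict[str, np.ndarray],
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    donor_id: str = "?",
) -> StepwiseFit:
    """Bidirectional stepwise OLS on partial t-test p-values.

    Start from the intercept-only model; repeatedly add the most
    significant excluded candidate with p < ``p_enter`` (ties broken by
    lexicographic term name), then drop any included term whose p exceeds
    ``p_remove``, until a fixed point.  The final refit on the selected
    terms yields standardized betas (y is standardized internally), the
    adjusted R^2 and the model F-test p; unselected terms get beta 0.
    """
    if p_enter > p_remove:
        raise ValueError("require p_enter <= p_remove")
    y = np.asarray(y, dtype=float).ravel()
    names = list(candidates)
    cand = {n: np.asarray(v, dtype=float).ravel() for n, v in candidates.items()}
    for n, v in cand.items():
        if v.size != y.size:
            raise ValueError(f"candidate {n!r} length mismatch")
    if y.size <= len(names) + 2:
        raise ValueError("need n_sites > n_candidates + 2")
    _check_collinear(cand)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: constant dependent variable")
    ys = (y - y.mean()) / sd

    selected: list[str] = []
    seen: set[tuple[str, ...]] = set()
    while True:
        state = tuple(selected)
        if state in seen:  # oscillation guard
            break
        seen.add(state)
        changed = False
        # entry step
        excluded = [n for n in names if n not in selected]
        entry = []
        for n in excluded:
            res = _fit_ols(ys, [cand[m] for m in selected] + [cand[n]])
            entry.append((float(res.pvalues[-1]), n))
        if entry:
            p_best, n_best = min(entry, key=lambda t: (t[0], t[1]))
            if p_best < p_enter:
                selected.append(n_best)
                selected.sort(key=names.index)
                changed = True
        # removal step
        while selected:
            pvals = _term_pvalues(ys, cand, selected)
            worst = max(pvals.items(), key=lambda kv: (kv[1], kv[0]))
            if worst[1] > p_remove:
                selected.remove(worst[0])
                changed = True
            else:
                break
        if not changed:
            break

    betas = {n: 0.0 for n in names}
    if selected:
        res = _fit_ols(ys, [cand[n] for n in selected])
        for i, n in enumerate(selected):
            betas[n] = float(res.params[i + 1])
        adj_r2 = float(res.rsquared_adj)
        model_p = float(res.f_pvalue)
    else:
        adj_r2, model_p = 0.0, 1.0
    return StepwiseFit(
        donor_id=donor_id,
        candidates=tuple(names),
        selected=tuple(selected),
        betas=betas,
        adj_r2=adj_r2,
        model_p=model_p,
    )


def random_effects_on_betas(
    fits: list[StepwiseFit],
) -> dict[str, RandomEffectsResult | None]:
    """One-sample t-test per candidate term over zero-imputed donor betas.

    Terms whose beta column has zero variance across donors (e.g. selected
    by no donor) are reported as not testable (``None``) rather than
    raising.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 donors")
    terms = fits[0].candidates
    out: dict[str, RandomEffectsResult | None] = {}
    for t in terms:
        betas = np.array([f.betas[t] for f in fits], dtype=float)
        if betas.std(ddof=1) == 0:
            out[t] = None
        else:
            out[t] = _one_sample_t(betas)
    return out
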