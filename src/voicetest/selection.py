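"""Stepwise item selection toward a Rasch-conforming test.

The workflow mirrors conformity-driven test shortening: starting from the
full item pool, (1) items with observed mean accuracy below the 3AFC
chance level (1/3) are dropped; (2) while a likelihood-ratio test prefers
the 2PL over the Rasch model (alpha = 0.05), the worst item under the 2PL
is eliminated and the models refit; (3) once the 2PL no longer fits
significantly better, elimination continues under the Rasch model, dropping
the worst ill-fitting item until every retained item passes the configured
infit/outfit bounds; (4) a DIF screen removes items whose difficulty
differs between groups.  Every elimination is logged with the statistic
that triggered it, so the whole path is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import irt
from .irt import FitResult, ResponseMatrix

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "SelectionAborted",
    "stepwise_select",
    "dif_screen",
    "finalize",
]

CHANCE_3AFC = 1.0 / 3.0


class SelectionAborted(RuntimeError):
    """Raised when elimination would go below the minimum retained items."""

    def __init__(self, message: str, trace: "SelectionTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class SelectionConfig:
    alpha: float = 0.05                  # LR-test level for 2PL vs Rasch
    chance: float = CHANCE_3AFC          # below-chance exclusion threshold
    fit_bounds: tuple[float, float] = (0.7, 1.3)  # infit/outfit acceptance band
    min_items: int = 10                  # abort threshold
    dif_alpha: float = 0.05              # per-item DIF level (BH-adjusted)
    min_group_size: int = 20
    n_quad: int = irt.DEFAULT_N_QUAD
    quad_range: float = irt.DEFAULT_QUAD_RANGE
    tol: float = irt.DEFAULT_TOL
    max_iter: int = irt.DEFAULT_MAX_ITER


@dataclass
class SelectionTrace:
    """Ordered elimination log plus model-switch bookkeeping."""

    initial_items: tuple[str, ...]
    eliminations: list[dict] = field(default_factory=list)  # item_id, step, reason, stats
    model_switch_step: int | None = None
    final_items: tuple[str, ...] = ()
    final_reliability: float | None = None
    fit_summaries: list[dict] = field(default_factory=list)

    def eliminate(self, item_id: str, step: int, reason: str, **stats) -> None:
        if reason not in ("below_chance", "ill_fitting", "dif"):
            raise ValueError(f"invalid elimination reason {reason!r}")
        self.eliminations.append({"item_id": item_id, "step": step, "reason": reason, **stats})

    @property
    def eliminated_items(self) -> list[str]:
        return [e["item_id"] for e in self.eliminations]

    def check(self) -> None:
        elim = self.eliminated_items
        if len(set(elim)) != len(elim):
            raise ValueError("item eliminated twice")
        if set(elim) | set(self.final_items) != set(self.initial_items):
            raise ValueError("eliminated and retained items do not partition the pool")
        if set(elim) & set(self.final_items):
            raise ValueError("eliminated and retained items overlap")

    def to_dict(self) -> dict:
        return {
            "initial_items": list(self.initial_items),
            "eliminations": self.eliminations,
            "model_switch_step": self.model_switch_step,
            "final_items": list(self.final_items),
            "final_reliability": self.final_reliability,
            "fit_summaries": self.fit_summaries,
        }


def _fit_pair(responses: ResponseMatrix, cfg: SelectionConfig):
    kw = dict(n_quad=cfg.n_quad, quad_range=cfg.quad_range, tol=cfg.tol,
              max_iter=cfg.max_iter, compute_se=False)
    rasch = irt.fit_rasch(responses, **kw)
    two_pl = irt.fit_2pl(responses, **kw)
    return rasch, two_pl


def _worst_item_2pl(two_pl: FitResult, fit_table: pd.DataFrame, rasch: FitResult) -> tuple[str, dict]:
    """Worst item under the 2PL: discrimination farthest from the common
    Rasch slope, then worst infit deviation, then item id (lexicographic)."""
    common_slope = rasch.latent_sd  # Rasch(sd=s) == 2PL with all a = s
    tbl = fit_table.set_index("item_id")
    scored = []
    for j, item in enumerate(two_pl.item_ids):
        a = two_pl.discrimination[j]
        if not np.isfinite(a):
            scored.append((np.inf, np.inf, item))
            continue
        dev_a = abs(a - common_slope)
        dev_fit = abs(tbl.loc[item, "infit"] - 1.0) if item in tbl.index else 0.0
        scored.append((dev_a, dev_fit, item))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    dev_a, dev_fit, item = scored[0]
    return item, {"discrimination_deviation": float(dev_a), "infit_deviation": float(dev_fit)}


def _worst_item_rasch(fit_table: pd.DataFrame, bounds) -> tuple[str, dict] | None:
    """Worst Rasch-violating item: largest |infit - 1| among items outside
    the fit bounds (considering both infit and outfit); None if all pass."""
    viol = fit_table[fit_table["flagged"]]
    if viol.empty:
        return None
    dev = np.maximum(np.abs(viol["infit"] - 1.0), np.abs(viol["outfit"] - 1.0))
    order = sorted(zip(-dev, viol["item_id"]))
    worst = order[0][1]
    row = fit_table.set_index("item_id").loc[worst]
    return worst, {"infit": float(row["infit"]), "outfit": float(row["outfit"])}


def stepwise_select(responses: ResponseMatrix, config: SelectionConfig | None = None) -> SelectionTrace:
    """Run the stepwise elimination loop and return the full trace.

    Deterministic for identical responses and configuration.  Raises
    :class:`SelectionAborted` (carrying the partial trace) if elimination
    would leave fewer than ``config.min_items`` items.
    """
    cfg = config or SelectionConfig()
    if responses.n_items < cfg.min_items:
        raise ValueError(f"need >= {cfg.min_items} items to start")
    trace = SelectionTrace(initial_items=tuple(responses.item_ids))
    current = responses
    step = 0

    # step 1: below-chance exclusions (observed accuracy over scored trials)
    acc = current.mean_accuracy()
    below = [(current.item_ids[j], float(acc[j])) for j in np.argsort(acc)
             if np.isfinite(acc[j]) and acc[j] < cfg.chance]
    for item, a in below:
        step += 1
        trace.eliminate(item, step, "below_chance", mean_accuracy=a)
    keep = [i for i in current.item_ids if i not in set(trace.eliminated_items)]
    current = current.with_items(keep)

    def record(rasch, two_pl, lr):
        trace.fit_summaries.append(
            {
                "step": step,
                "n_items": current.n_items,
                "rasch_loglik": rasch.loglik,
                "rasch_bic": rasch.bic,
                "2pl_loglik": two_pl.loglik,
                "2pl_bic": two_pl.bic,
                "lr_chi2": lr.chi2,
                "lr_df": lr.df,
                "lr_p": lr.p,
            }
        )

    # step 2: eliminate under the 2PL while it beats the Rasch model
    while True:
        if current.n_items < cfg.min_items:
            trace.final_items = tuple(current.item_ids)
            raise SelectionAborted(
                f"fewer than {cfg.min_items} items remain", trace
            )
        rasch, two_pl = _fit_pair(current, cfg)
        lr = irt.lr_test(rasch, two_pl)
        record(rasch, two_pl, lr)
        if lr.p >= cfg.alpha:
            trace.model_switch_step = step
            break
        fit_tbl = irt.item_fit(two_pl, current, bounds=cfg.fit_bounds)
        item, stats = _worst_item_2pl(two_pl, fit_tbl, rasch)
        step += 1
        trace.eliminate(item, step, "ill_fitting", model="2pl", lr_p=lr.p, **stats)
        current = current.with_items([i for i in current.item_ids if i != item])

    # step 3: continue under the Rasch model until all items pass fit bounds
    while True:
        rasch = irt.fit_rasch(current, n_quad=cfg.n_quad, quad_range=cfg.quad_range,
                              tol=cfg.tol, max_iter=cfg.max_iter, compute_se=False)
        fit_tbl = irt.item_fit(rasch, current, bounds=cfg.fit_bounds)
        worst = _worst_item_rasch(fit_tbl, cfg.fit_bounds)
        if worst is None:
            break
        if current.n_items - 1 < cfg.min_items:
            trace.final_items = tuple(current.item_ids)
            raise SelectionAborted(
                f"fewer than {cfg.min_items} items would remain", trace
            )
        item, stats = worst
        step += 1
        trace.eliminate(item, step, "ill_fitting", model="rasch", **stats)
        current = current.with_items([i for i in current.item_ids if i != item])

    trace.final_items = tuple(current.item_ids)
    trace.check()
    return trace


def dif_screen(
    responses: ResponseMatrix,
    retained_items,
    groupings,
    trace: SelectionTrace | None = None,
    config: SelectionConfig | None = None,
):
    """Screen retained items for DIF and exclude flagged ones.

    Per grouping variable, runs the two-group Rasch DIF test; per-item
    p-values are Benjamini-Hochberg adjusted across items within the
    grouping and items significant at ``config.dif_alpha`` are excluded
    with reason ``dif``.

    Returns ``(surviving_items, trace)``.
    """
    cfg = config or SelectionConfig()
    if not groupings:
        raise ValueError("at least one grouping variable required")
    sub = responses.with_items(list(retained_items))
    if trace is None:
        trace = SelectionTrace(initial_items=tuple(retained_items))
    step = max((e["step"] for e in trace.eliminations), default=0)
    excluded: dict[str, dict] = {}
    for grouping in groupings:
        result = irt.dif_test(sub, grouping, min_group_size=cfg.min_group_size,
                              n_quad=cfg.n_quad, quad_range=cfg.quad_range,
                              tol=cfg.tol, max_iter=cfg.max_iter)
        tbl = result.item_table.dropna(subset=["p"]).copy()
        p_adj = _stats.false_discovery_control(tbl["p"].to_numpy(), method="bh")
        tbl["p_adj"] = p_adj
        trace.fit_summaries.append(
            {"step": step, "dif_grouping": grouping, "dif_chi2": result.chi2,
             "dif_df": result.df, "dif_p": result.p}
        )
        for row in tbl.itertuples(index=False):
            if row.p_adj < cfg.dif_alpha and row.item_id not in excluded:
                excluded[row.item_id] = {
                    "grouping": grouping,
                    "delta_b": float(row.delta_b),
                    "p_adj": float(row.p_adj),
                }
    for item, stats_ in sorted(excluded.items()):
        step += 1
        trace.eliminate(item, step, "dif", **stats_)
    surviving = [i for i in retained_items if i not in excluded]
    return surviving, trace


def finalize(responses: ResponseMatrix, trace: SelectionTrace,
             config: SelectionConfig | None = None) -> dict:
    """Refit the Rasch model on the final item set and report it.

    The report carries difficulties with SEs, EAP-based empirical marginal
    reliability, the test information curve, and the BIC adjudication
    against a 2PL refit on the same items (parsimony check on the final
    set).  The reported reliability is recomputed from the emitted ability
    estimates, so it is internally consistent by construction.
    """
    cfg = config or SelectionConfig()
    final = responses.with_items(list(trace.final_items))
    kw = dict(n_quad=cfg.n_quad, quad_range=cfg.quad_range, tol=cfg.tol, max_iter=cfg.max_iter)
    rasch = irt.fit_rasch(final, compute_se=True, **kw)
    two_pl = irt.fit_2pl(final, compute_se=False, **kw)
    abilities = irt.eap_abilities(rasch, final)
    reliability = irt.empirical_reliability(abilities)
    trace.final_reliability = reliability
    theta, info, se = irt.test_information(rasch)
    return {
        "final_items": list(trace.final_items),
        "rasch_fit": rasch,
        "abilities": abilities,
        "empirical_reliability": reliability,
        "information": {"theta": theta, "information": info, "se": se},
        "bic_rasch": rasch.bic,
        "bic_2pl": two_pl.bic,
        "rasch_preferred_by_bic": rasch.bic < two_pl.bic,
        "trace": trace,
    }
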