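"""iMAT: context-specific reaction activity from expression categories.

Given per-sample gene categories, each reaction's state is the GPR tree folded
with AND -> min and OR -> max over the order low < moderate < high; reactions
resolving to *high* form R_H, to *low* R_L (reactions without a GPR are never
members).  The iMAT mixed-integer program then finds a mass-balanced flux
distribution maximizing the number of agreements with those states:

    max   sum_{i in R_H} (y+_i + y-_i)  +  sum_{i in R_L} x_i
    s.t.  S v = 0,   lb <= v <= ub
          i in R_H:  v_i + y+_i (lb_i - eps) >= lb_i        (y+=1 -> v_i >= eps)
                     v_i + y-_i (ub_i + eps) <= ub_i        (y-=1 -> v_i <= -eps)
                     y+_i + y-_i <= 1
          i in R_L:  lb_i (1 - x_i) <= v_i <= ub_i (1 - x_i)  (x=1 -> v_i = 0)

with all y, x binary.  eps is the minimum magnitude for "carrying flux"
(default 1.0 against bounds of +-1000).  The solved flux vector is binarized
into an activity column: active (1) iff |v_i| exceeds ``activity_tol``.

The MILP is solved with HiGHS through ``scipy.optimize.milp``; HiGHS is
deterministic at fixed inputs, so identical samples yield identical columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, milp

from .expression import GeneCategoryTable, LOW, MODERATE, HIGH
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "ImatConfig",
    "ImatSolution",
    "ReactionStateInput",
    "ActivityMatrix",
    "InfeasibleModelError",
    "gene_states_to_reaction_sets",
    "reaction_category",
    "solve_imat",
    "binarize",
    "run_imat_all",
    "binary_pca",
]

_LEVEL = {LOW: 0, MODERATE: 1, HIGH: 2}


class InfeasibleModelError(RuntimeError):
    """The steady-state system S v = 0 has no solution within bounds."""


@dataclass(frozen=True)
class ImatConfig:
    epsilon: float = 1.0          # minimum |flux| for "carrying flux"
    activity_tol: float = 1e-6    # |v| threshold for calling a reaction active
    mip_gap: float = 1e-6         # relative optimality gap
    time_limit: float | None = None  # seconds per solve
    seed: int = 0                 # kept for interface parity; HiGHS is deterministic

    def __post_init__(self):
        if not (0 < self.activity_tol < self.epsilon):
            raise ValueError("require 0 < activity_tol < epsilon")
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be >= 0")


@dataclass
class ReactionStateInput:
    """Per-sample highly/lowly expressed reaction sets."""

    per_sample: dict[str, tuple[set[str], set[str]]]  # sample -> (R_H, R_L)

    def __post_init__(self):
        for s, (rh, rl) in self.per_sample.items():
            if rh & rl:
                raise ValueError(f"sample {s!r}: R_H and R_L overlap: {sorted(rh & rl)}")


@dataclass
class ImatSolution:
    fluxes: pd.Series              # reaction id -> flux
    objective: int                 # satisfied-state recount from the fluxes
    solver_objective: float        # MILP incumbent objective
    indicators: dict[str, dict]    # reaction id -> indicator values
    status: str

    def __post_init__(self):
        # the flux recount may exceed the solver objective (a flux can satisfy
        # a state whose indicator stayed 0) but must never fall below it
        if self.objective < self.solver_objective - 1e-6:
            raise RuntimeError("recounted objective below solver objective")


@dataclass
class ActivityMatrix:
    """Binary reactions x samples activity matrix."""

    data: pd.DataFrame  # entries in {0,1}

    def __post_init__(self):
        vals = self.data.values
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("activity matrix must be binary")

    @property
    def reactions(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Gene categories -> reaction sets
# ---------------------------------------------------------------------------

def reaction_category(gpr, categories: dict[str, str]) -> str | None:
    """Fold a GPR over categories with AND->min / OR->max; None for empty GPR."""
    levels = {g: _LEVEL.get(c, 1) for g, c in categories.items()}
    val = gpr.evaluate(levels, default=_LEVEL[MODERATE])
    if val is None:
        return None
    return (LOW, MODERATE, HIGH)[val]


def gene_states_to_reaction_sets(
    model: MetabolicModel, categories: GeneCategoryTable
) -> ReactionStateInput:
    """Map per-sample gene categories to per-sample (R_H, R_L) reaction sets.

    Genes absent from the category table (e.g. removed by the expression
    filter) are treated as moderate.
    """
    per_sample: dict[str, tuple[set[str], set[str]]] = {}
    for sample in categories.categories.columns:
        cat = categories.sample_categories(sample)
        rh: set[str] = set()
        rl: set[str] = set()
        for r in model.reactions:
            state = reaction_category(r.gpr, cat)
            if state == HIGH:
                rh.add(r.id)
            elif state == LOW:
                rl.add(r.id)
        per_sample[sample] = (rh, rl)
    return ReactionStateInput(per_sample=per_sample)


# ---------------------------------------------------------------------------
# The MILP
# ---------------------------------------------------------------------------

def _recount_satisfied(model, fluxes, rh, rl, cfg) -> int:
    n = 0
    slack = 1e-6 * max(1.0, cfg.epsilon)
    for rid in rh:
        if abs(fluxes[rid]) >= cfg.epsilon - slack:
            n += 1
    for rid in rl:
        if abs(fluxes[rid]) <= cfg.activity_tol:
            n += 1
    return n


def solve_imat(
    model: MetabolicModel, rh: set[str], rl: set[str], cfg: ImatConfig = ImatConfig()
) -> ImatSolution:
    """Solve the iMAT MILP for one sample's (R_H, R_L) reaction sets."""
    unknown = (rh | rl) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reaction ids in R_H/R_L: {sorted(unknown)}")
    if rh & rl:
        raise ValueError("R_H and R_L overlap")

    n_rxn = len(model.reactions)
    rxn_pos = {r.id: j for j, r in enumerate(model.reactions)}
    rh_list = sorted(rh)
    rl_list = sorted(rl)
    n_var = n_rxn + 2 * len(rh_list) + len(rl_list)
    yp0 = n_rxn
    ym0 = n_rxn + len(rh_list)
    x0 = n_rxn + 2 * len(rh_list)

    lb = np.empty(n_var)
    ub = np.empty(n_var)
    for j, r in enumerate(model.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
    lb[n_rxn:] = 0.0
    ub[n_rxn:] = 1.0
    integrality = np.zeros(n_var)
    integrality[n_rxn:] = 1

    c = np.zeros(n_var)
    c[n_rxn:] = -1.0  # maximize the number of satisfied states

    rows, cols, data, c_lo, c_hi = [], [], [], [], []
    nrow = 0

    def add_row(entries, lo, hi):
        nonlocal nrow
        for col, val in entries:
            rows.append(nrow)
            cols.append(col)
            data.append(val)
        c_lo.append(lo)
        c_hi.append(hi)
        nrow += 1

    # mass balance S v = 0
    S = model.S.tocoo()
    for i, j, v in zip(S.row, S.col, S.data):
        rows.append(nrow + i)
        cols.append(j)
        data.append(v)
    for _ in range(S.shape[0]):
        c_lo.append(0.0)
        c_hi.append(0.0)
    nrow += S.shape[0]

    eps = cfg.epsilon
    for k, rid in enumerate(rh_list):
        j = rxn_pos[rid]
        r = model.reactions[j]
        # y+ = 1 forces v >= eps
        add_row([(j, 1.0), (yp0 + k, r.lower_bound - eps)], r.lower_bound, np.inf)
        # y- = 1 forces v <= -eps
        add_row([(j, 1.0), (ym0 + k, r.upper_bound + eps)], -np.inf, r.upper_bound)
        add_row([(yp0 + k, 1.0), (ym0 + k, 1.0)], -np.inf, 1.0)
    for k, rid in enumerate(rl_list):
        j = rxn_pos[rid]
        r = model.reactions[j]
        # x = 1 forces v = 0
        add_row([(j, 1.0), (x0 + k, r.lower_bound)], r.lower_bound, np.inf)
        add_row([(j, 1.0), (x0 + k, r.upper_bound)], -np.inf, r.upper_bound)

    A = sparse.csr_matrix((data, (rows, cols)), shape=(nrow, n_var))
    constraints = LinearConstraint(A, np.array(c_lo), np.array(c_hi))
    options: dict = {"mip_rel_gap": cfg.mip_gap}
    if cfg.time_limit is not None:
        options["time_limit"] = cfg.time_limit
    res = milp(
        c=c,
        constraints=constraints,
        bounds=Bounds(lb, ub),
        integrality=integrality,
        options=options,
    )
    if res.status == 2 or res.x is None:  # infeasible / no incumbent
        raise InfeasibleModelError(f"iMAT MILP infeasible or no incumbent: {res.message}")

    v = res.x[:n_rxn]
    # verify the solution against the model's own invariants
    resid = np.abs(model.S @ v)
    tol = 1e-6 * max(1.0, float(np.max(np.abs(v))) if n_rxn else 1.0)
    if resid.size and resid.max() > tol:
        raise RuntimeError(f"mass-balance residual {resid.max():.3g} exceeds tolerance")
    for j, r in enumerate(model.reactions):
        if not (r.lower_bound - 1e-6 <= v[j] <= r.upper_bound + 1e-6):
            raise RuntimeError(f"flux bound violated for {r.id}")

    fluxes = pd.Series(v, index=model.reaction_ids, name="flux")
    indicators = {}
    for k, rid in enumerate(rh_list):
        indicators[rid] = {
            "y_plus": int(round(res.x[yp0 + k])),
            "y_minus": int(round(res.x[ym0 + k])),
        }
    for k, rid in enumerate(rl_list):
        indicators[rid] = {"x": int(round(res.x[x0 + k]))}
    recount = _recount_satisfied(model, fluxes, rh, rl, cfg)
    return ImatSolution(
        fluxes=fluxes,
        objective=recount,
        solver_objective=float(-res.fun),
        indicators=indicators,
        status="optimal" if res.status == 0 else res.message,
    )


def binarize(sol: ImatSolution, cfg: ImatConfig = ImatConfig()) -> pd.Series:
    """Activity column: 1 iff |v_i| > activity_tol."""
    return (sol.fluxes.abs() > cfg.activity_tol).astype(int)


def run_imat_all(
    model: MetabolicModel, rsi: ReactionStateInput, cfg: ImatConfig = ImatConfig()
) -> ActivityMatrix:
    """One iMAT solve per sample, assembled into an ActivityMatrix."""
    if not rsi.per_sample:
        raise ValueError("no samples to solve")
    cols = {}
    for sample, (rh, rl) in rsi.per_sample.items():
        try:
            sol = solve_imat(model, rh, rl, cfg)
        except Exception as exc:
            raise RuntimeError(f"iMAT failed for sample {sample!r}: {exc}") from exc
        if sol.objective > len(rh) + len(rl):
            raise RuntimeError("objective exceeds |R_H| + |R_L|")
        col = binarize(sol, cfg)
        logger.info(
            "iMAT %s: objective %d/%d, %d active reactions",
            sample, sol.objective, len(rh) + len(rl), int(col.sum()),
        )
        cols[sample] = col
    df = pd.DataFrame(cols, columns=list(rsi.per_sample))
    return ActivityMatrix(data=df)


def binary_pca(am: ActivityMatrix, n_components: int = 2):
    """Ordinary PCA of the binary activity columns (samples as observations).

    Returns (scores DataFrame samples x components, explained variance ratios).
    Provided for QC of sample similarity structure.
    """
    from sklearn.decomposition import PCA

    X = am.data.values.T.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    k = max(k, 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=am.samples, columns=cols),
        pca.explained_variance_ratio_,
    )
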