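"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the package's own solver /
statistic code paths: the iMAT oracle enumerates activity-support patterns
with plain LP feasibility checks, and the Fisher oracle sums hypergeometric
tail probabilities directly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.stats import hypergeom

from gemcentric.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_in -> A --R1--> B -> EX_out, all bounds [0, 10], R1 carries gene g1."""
    mets = [Metabolite("A[c]"), Metabolite("B[c]")]
    rxns = [
        Reaction("EX_in", {"A[c]": 1.0}, 0.0, 10.0, parse_gpr("")),
        Reaction("R1", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 10.0, parse_gpr("g1")),
        Reaction("EX_out", {"B[c]": -1.0}, 0.0, 10.0, parse_gpr("")),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns)


@pytest.fixture
def toy_model_file(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "reaction_id\tequation\tlb\tub\tgpr\n"
        "EX_A\t -> A[c]\t0\t10\t\n"
        "R1\tA[c] -> B[c]\t0\t10\tg1\n"
        "R2\tB[c] <-> C[m]\t-10\t10\t(g2 or g3)\n"
        "R3\t2 C[m] -> D[c]\t0\t10\tg1 and g4\n"
        "EX_D\tD[c] -> \t0\t10\t\n"
        "EX_C\tC[m] -> \t0\t10\t\n"
    )
    return path


# ---------------------------------------------------------------------------
# iMAT oracle: exhaustive support-pattern enumeration with LP feasibility
# ---------------------------------------------------------------------------

def imat_enumeration_oracle(model: MetabolicModel, rh: set, rl: set, eps: float) -> int:
    """Max number of satisfiable high/low states, by brute force.

    Every assignment of each R_H reaction to {unsatisfied, forward >= eps,
    backward <= -eps} and each R_L reaction to {unsatisfied, flux = 0} is
    checked for LP feasibility against S v = 0 and the bounds; the maximum
    satisfied count over feasible assignments is returned.
    """
    n = len(model.reactions)
    pos = {r.id: j for j, r in enumerate(model.reactions)}
    S = model.S.toarray()
    base_lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    base_ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    rh_list, rl_list = sorted(rh), sorted(rl)
    best = -1
    for hi_states in itertools.product((0, 1, 2), repeat=len(rh_list)):
        for lo_states in itertools.product((0, 1), repeat=len(rl_list)):
            lb, ub = base_lb.copy(), base_ub.copy()
            ok = True
            for rid, st in zip(rh_list, hi_states):
                j = pos[rid]
                if st == 1:
                    lb[j] = max(lb[j], eps)
                elif st == 2:
                    ub[j] = min(ub[j], -eps)
                if lb[j] > ub[j]:
                    ok = False
            for rid, st in zip(rl_list, lo_states):
                j = pos[rid]
                if st == 1:
                    lb[j], ub[j] = max(lb[j], 0.0), min(ub[j], 0.0)
                if lb[j] > ub[j]:
                    ok = False
            score = sum(1 for s in hi_states if s) + sum(lo_states)
            if not ok or score <= best:
                continue
            res = linprog(
                c=np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lb, ub)), method="highs",
            )
            if res.status == 0:
                best = score
    return best


def random_toy_instance(rng: np.random.Generator):
    """A random small network (<= 12 reactions) plus random R_H / R_L sets."""
    n_met = int(rng.integers(2, 5))
    met_ids = [f"M{i}[c]" for i in range(n_met)]
    rxns = []
    n_int = int(rng.integers(2, 7))
    for i in range(n_int):
        a, b = rng.choice(n_met, size=2, replace=False)
        reversible = bool(rng.random() < 0.4)
        rxns.append(
            Reaction(
                f"R{i}", {met_ids[a]: -1.0, met_ids[b]: 1.0},
                -10.0 if reversible else 0.0, 10.0, parse_gpr(f"g{i}"),
            )
        )
    for i in range(n_met):
        if rng.random() < 0.7 and len(rxns) < 11:
            rxns.append(Reaction(f"EXin{i}", {met_ids[i]: 1.0}, 0.0, 10.0, parse_gpr("")))
        if rng.random() < 0.7 and len(rxns) < 12:
            rxns.append(Reaction(f"EXout{i}", {met_ids[i]: -1.0}, 0.0, 10.0, parse_gpr("")))
    model = MetabolicModel(metabolites=[Metabolite(m) for m in met_ids], reactions=rxns)
    gpr_rxns = [r.id for r in rxns if not r.gpr.is_empty]
    rng.shuffle(gpr_rxns)
    n_h = int(rng.integers(0, min(3, len(gpr_rxns)) + 1))
    n_l = int(rng.integers(0, min(3, len(gpr_rxns) - n_h) + 1))
    return model, set(gpr_rxns[:n_h]), set(gpr_rxns[n_h : n_h + n_l])


# ---------------------------------------------------------------------------
# Fisher oracle: exhaustive hypergeometric tail enumeration
# ---------------------------------------------------------------------------

def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]]: sum of the probabilities of
    all tables with the same margins whose probability does not exceed the
    observed table's (with the customary 1 + 1e-7 relative slack)."""
    r1, n = a + b, a + b + c + d
    k = a + c
    lo, hi = max(0, k - (n - r1)), min(k, r1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, n, r1, k)
    p_obs = hypergeom.pmf(a, n, r1, k)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
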