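"""Genome-scale metabolic model input/output.

A metabolic model is held as explicit metabolite / reaction lists plus a
sparse stoichiometric matrix ``S`` (metabolites x reactions).  Reactions carry
flux bounds and a boolean gene-protein-reaction (GPR) rule over gene
identifiers; the GPR is the bridge between expression data and the network.

Two dialects are supported: SBML Level 3 with FBC (read through COBRApy) for
real genome-scale models, and a small tab-separated "toy model" dialect used
for fixtures and synthetic networks::

    reaction_id  equation                 lb    ub    gpr
    R1           A[c] + B[c] -> C[c]      0     10    g1 and (g2 or g3)

``->`` marks an irreversible reaction (lower bound clamped at 0), ``<->`` a
reversible one.  Compartments are bracketed suffixes (``glc[c]``); ``base_id``
is the identifier with the compartment tag stripped, which is the unit that
pathway annotation tables key on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Gpr",
    "Reaction",
    "MetabolicModel",
    "GprParseError",
    "ModelIntegrityError",
    "ToyModelParseError",
    "parse_gpr",
    "read_toy_model",
    "write_toy_model",
    "read_sbml",
    "strip_compartment",
    "model_summary",
]

DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)

#: default pattern for a trailing compartment tag: "[c]" or "_c" style suffixes
COMPARTMENT_PATTERN = re.compile(r"(?:\[([A-Za-z0-9]{1,3})\]|_([a-z][a-z0-9]?))$")


class GprParseError(ValueError):
    """Raised when a gene-association string cannot be parsed."""


class ModelIntegrityError(ValueError):
    """Raised when a model violates its structural invariants."""


class ToyModelParseError(ValueError):
    """Raised on malformed toy-model TSV input; carries the line number."""


def strip_compartment(met_id: str, pattern: re.Pattern = COMPARTMENT_PATTERN) -> tuple[str, str]:
    """Split a metabolite id into (base_id, compartment).

    Falls back to compartment ``"c"`` when no tag is recognised, so every
    metabolite has a non-empty compartment code.
    """
    m = pattern.search(met_id)
    if m:
        comp = m.group(1) or m.group(2)
        base = met_id[: m.start()]
        if base:
            return base, comp
    return met_id, "c"


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    base_id: str = ""

    def __post_init__(self):
        if not self.base_id:
            object.__setattr__(self, "base_id", strip_compartment(self.id)[0])
        if not self.base_id or not self.compartment:
            raise ModelIntegrityError(f"metabolite {self.id!r}: empty base_id or compartment")


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

# A GPR tree node is ("gene", name) | ("and", [nodes]) | ("or", [nodes]).
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class Gpr:
    """Boolean AND/OR tree over gene identifiers; ``root is None`` = no rule."""

    root: tuple | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node is None:
                return
            kind = node[0]
            if kind == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self.root)
        return frozenset(out)

    def to_string(self) -> str:
        def render(node, parent: str | None) -> str:
            kind = node[0]
            if kind == "gene":
                return node[1]
            sep = f" {kind} "
            body = sep.join(render(c, kind) for c in node[1])
            # "and" binds tighter than "or": parenthesize only or-under-and
            if parent == "and" and kind == "or":
                return f"({body})"
            return body

        return "" if self.root is None else render(self.root, None)

    def evaluate(self, values: dict[str, int], default: int) -> int | None:
        """Fold the tree with AND->min, OR->max over integer-coded levels.

        Returns ``None`` for an empty rule.  Genes absent from ``values`` take
        ``default`` (used for genes filtered out upstream: treated moderate).
        """
        if self.root is None:
            return None

        def walk(node) -> int:
            kind = node[0]
            if kind == "gene":
                return values.get(node[1], default)
            folded = [walk(c) for c in node[1]]
            return min(folded) if kind == "and" else max(folded)

        return walk(self.root)


def parse_gpr(text: str) -> Gpr:
    """Parse a gene-association string ("g1 and (g2 or g3)") into a :class:`Gpr`.

    Connectives are case-insensitive; an empty/whitespace string yields the
    empty rule.  Unbalanced parentheses or dangling connectives raise
    :class:`GprParseError`.
    """
    if text is None or not text.strip():
        return Gpr(None)
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", tuple(terms))

    def parse_and():
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", tuple(factors))

    def parse_atom():
        tok = take()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            inner = parse_or()
            if take() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR: {text!r}")
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return ("gene", tok)

    root = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR: {text!r}")
    return Gpr(root)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Gpr = field(default_factory=Gpr)

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(f"reaction {self.id!r}: lb > ub")
        if not self.stoichiometry:
            raise ModelIntegrityError(f"reaction {self.id!r}: empty stoichiometry")
        if any(coef == 0 for coef in self.stoichiometry.values()):
            raise ModelIntegrityError(f"reaction {self.id!r}: zero stoichiometric coefficient")


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    S: sparse.csc_matrix | None = None

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelIntegrityError("duplicate reaction ids")
        if len(self._met_index) != len(self.metabolites):
            raise ModelIntegrityError("duplicate metabolite ids")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ModelIntegrityError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
        gene_union = sorted(set().union(*[r.gpr.genes for r in self.reactions]) if self.reactions else set())
        if not self.genes:
            self.genes = gene_union
        elif sorted(self.genes) != gene_union:
            raise ModelIntegrityError("gene list does not equal the union of GPR leaves")
        if self.S is None:
            self.S = self._build_s()
        self._check_s()
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    def _build_s(self) -> sparse.csc_matrix:
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(self._met_index[mid])
                cols.append(j)
                data.append(coef)
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def _check_s(self):
        # S column j must reproduce reaction j's stoichiometry map exactly
        S = self.S.tocsc()
        if S.shape != (len(self.metabolites), len(self.reactions)):
            raise ModelIntegrityError("S shape mismatch")
        for j, r in enumerate(self.reactions):
            col = S.getcol(j)
            entries = {self.metabolites[i].id: v for i, v in zip(col.indices, col.data)}
            if entries != r.stoichiometry:
                raise ModelIntegrityError(f"S column for {r.id!r} disagrees with stoichiometry")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]


# ---------------------------------------------------------------------------
# Toy-model TSV dialect
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_equation(eq: str, lineno: int) -> tuple[dict[str, float], bool]:
    if "<->" in eq:
        lhs, rhs = eq.split("<->", 1)
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->", 1)
        reversible = False
    else:
        raise ToyModelParseError(f"line {lineno}: equation missing '->' or '<->': {eq!r}")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return  # exchange reactions may have an empty side
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if not m or m.group(2) in ("+", "-"):
                raise ToyModelParseError(f"line {lineno}: unparseable term {term!r} in {eq!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            mid = m.group(2)
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef
    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise ToyModelParseError(f"line {lineno}: equation has empty stoichiometry: {eq!r}")
    return stoich, reversible


def read_toy_model(path) -> MetabolicModel:
    """Read the tab-separated toy-model dialect (see module docstring)."""
    reactions: list[Reaction] = []
    met_ids: dict[str, None] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "reaction_id":
                continue
            if len(parts) < 5:
                raise ToyModelParseError(f"line {lineno}: expected 5 tab-separated fields")
            rid, eq, lb_s, ub_s, gpr_s = (p.strip() for p in parts[:5])
            stoich, reversible = _parse_equation(eq, lineno)
            try:
                lb = float(lb_s) if lb_s else (
                    DEFAULT_REVERSIBLE_BOUNDS[0] if reversible else DEFAULT_IRREVERSIBLE_BOUNDS[0]
                )
                ub = float(ub_s) if ub_s else DEFAULT_REVERSIBLE_BOUNDS[1]
            except ValueError:
                raise ToyModelParseError(f"line {lineno}: non-numeric bound") from None
            if not reversible:
                lb = max(lb, 0.0)
            reactions.append(Reaction(rid, stoich, lb, ub, parse_gpr(gpr_s)))
            for mid in stoich:
                met_ids.setdefault(mid)
    metabolites = [Metabolite(mid, compartment=strip_compartment(mid)[1]) for mid in met_ids]
    return MetabolicModel(metabolites=metabolites, reactions=reactions)


def write_toy_model(model: MetabolicModel, path) -> None:
    """Write a model in the toy dialect; inverse of :func:`read_toy_model`."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tequation\tlb\tub\tgpr\n")
        for r in model.reactions:
            subs = [(m, -c) for m, c in r.stoichiometry.items() if c < 0]
            prods = [(m, c) for m, c in r.stoichiometry.items() if c > 0]

            def side(terms):
                return " + ".join(
                    (f"{c:g} {m}" if c != 1 else m) for m, c in sorted(terms)
                )
            arrow = "<->" if r.lower_bound < 0 else "->"
            fh.write(
                f"{r.id}\t{side(subs)} {arrow} {side(prods)}\t{r.lower_bound:g}"
                f"\t{r.upper_bound:g}\t{r.gpr.to_string()}\n"
            )


# ---------------------------------------------------------------------------
# SBML (via COBRApy)
# ---------------------------------------------------------------------------

def read_sbml(path) -> MetabolicModel:
    """Read an SBML L3/FBC model into a :class:`MetabolicModel`.

    Parsing is delegated to COBRApy; bounds come from FBC parameters and GPR
    strings are re-parsed by :func:`parse_gpr` so that category evaluation
    uses this package's min/max semantics.  Missing bounds fall back to the
    conventional [-1000, 1000] / [0, 1000] defaults.
    """
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various SBML errors
        raise ToyModelParseError(f"SBML parse failure for {path}: {exc}") from exc

    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            base_id=strip_compartment(m.id)[0],
        )
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
            )
        )
    return MetabolicModel(metabolites=metabolites, reactions=reactions)


def model_summary(model: MetabolicModel) -> dict:
    """Counts of reactions / metabolites / genes, JSON-serialisable."""
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(model.genes),
    }


def write_model_summary(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_summary(model), fh, indent=2)
        fh.write("\n")
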