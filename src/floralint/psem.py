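"""Phylogenetic piecewise structural equation models.

A path model is a DAG over species-level variables (a pollinator predictor
plus floral traits grouped into accessibility, efficiency and
attractiveness modules) together with correlated-error pairs for
associations that are not given a causal direction.  Each structural
equation (one per endogenous vertex) is fitted by PGLS; the model as a
whole is evaluated with Shipley's d-separation test: every conditional
independence the DAG implies but does not model is tested as a regression,
and the claim p-values are combined into Fisher's C = -2 * sum(ln p_i),
which is chi-squared with 2k degrees of freedom when the model is correct.
Candidate models are ranked by AIC = C + 2K over the fits whose C test
does not reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import pgls as _pgls
from .errors import ValidationError
from .trees import PhyloTree

__all__ = [
    "PathModel",
    "IndependenceClaim",
    "PSEMFit",
    "build_path_model",
    "basis_set",
    "test_claim",
    "fit_psem",
    "fisher_c",
    "enumerate_candidate_models",
    "load_model_family",
    "select_best",
]

#: canonical variable set and functional-module tags
DEFAULT_TAGS = {
    "PLa": "predictor",
    "tube": "accessibility",
    "stigma": "efficiency",
    "upper": "attractiveness",
    "lower": "attractiveness",
}


@dataclass
class PathModel:
    """DAG plus correlated-error pairs over labelled variables."""

    vertices: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    correlated_errors: tuple[frozenset, ...]
    tags: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.vertices = tuple(self.vertices)
        self.edges = tuple(self.edges)
        self.correlated_errors = tuple(frozenset(p) for p in self.correlated_errors)
        g = self.graph()
        self._topo = tuple(nx.lexicographical_topological_sort(g))

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._topo

    def parents(self, v: str) -> set[str]:
        return {a for a, b in self.edges if b == v}

    def endogenous(self) -> list[str]:
        """Vertices with at least one directed parent, in topological order."""
        return [v for v in self._topo if self.parents(v)]

    def exogenous(self) -> set[str]:
        return {v for v in self.vertices if not self.parents(v)}

    def adjacent(self, u: str, v: str) -> bool:
        return (u, v) in self.edges or (v, u) in self.edges


def build_path_model(
    edges,
    correlated_errors=(),
    tags: dict | None = None,
    vertices=None,
    name: str = "",
) -> PathModel:
    """Validate and build a path model.

    Raises on cycles (listing one), on an edge and a correlated error
    between the same pair, and on correlated-error endpoints that are
    adjacent in the directed graph.
    """
    edges = tuple((str(a), str(b)) for a, b in edges)
    ces = tuple(frozenset(map(str, p)) for p in correlated_errors)
    verts = set(vertices or ())
    for a, b in edges:
        verts.update((a, b))
    for p in ces:
        if len(p) != 2:
            raise ValidationError(f"correlated error must join two distinct vertices: {sorted(p)}")
        verts.update(p)
    g = nx.DiGraph()
    g.add_nodes_from(verts)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValidationError(f"path model contains a cycle: {cycle}")
    if len(set(edges)) != len(edges):
        raise ValidationError("duplicate directed edge")
    for p in ces:
        a, b = sorted(p)
        if (a, b) in edges or (b, a) in edges:
            raise ValidationError(
                f"conflict: both a directed edge and a correlated error between {a} and {b}"
            )
    tags = dict(tags or {})
    return PathModel(
        vertices=tuple(sorted(verts)),
        edges=edges,
        correlated_errors=ces,
        tags=tags,
        name=name,
    )


@dataclass
class IndependenceClaim:
    """One d-separation claim: u and v independent given the conditioning set."""

    u: str
    v: str
    conditioning: tuple[str, ...]
    response: str  # the vertex regressed in the claim test
    p: float | None = None
    coefficient: float | None = None
    model: str | None = None

    @property
    def other(self) -> str:
        return self.v if self.response == self.u else self.u


def _designate_response(model: PathModel, u: str, v: str, conditioning) -> str:
    """Pick the regression response of a claim.

    The vertex later in topological order is used when one has directed
    ancestry over the other; otherwise the vertex whose parent set overlaps
    the conditioning set more, with ties broken by label order (the later
    label is the response).
    """
    g = model.graph()
    if nx.has_path(g, u, v):
        return v
    if nx.has_path(g, v, u):
        return u
    cond = set(conditioning)
    ou = len(model.parents(u) & cond)
    ov = len(model.parents(v) & cond)
    if ou != ov:
        return u if ou > ov else v
    return max(u, v)


def basis_set(model: PathModel) -> list[IndependenceClaim]:
    """Shipley's d-separation basis set of a path model.

    One claim per unordered vertex pair that is (a) non-adjacent in the
    directed graph, (b) not a correlated-error pair, and (c) not composed
    of two exogenous vertices.  The conditioning set is the union of the
    two vertices' parents.  Claims are ordered canonically: by topological
    position of the pair, then label.
    """
    exo = model.exogenous()
    pos = {v: i for i, v in enumerate(model.topological_order)}
    claims = []
    verts = sorted(model.vertices)
    for i, u in enumerate(verts):
        for v in verts[i + 1 :]:
            if model.adjacent(u, v):
                continue
            if frozenset((u, v)) in model.correlated_errors:
                continue
            if u in exo and v in exo:
                continue
            cond = tuple(sorted((model.parents(u) | model.parents(v)) - {u, v}))
            a, b = sorted((u, v), key=lambda x: (pos[x], x))
            claims.append(
                IndependenceClaim(
                    u=a, v=b, conditioning=cond,
                    response=_designate_response(model, a, b, cond),
                )
            )
    claims.sort(key=lambda c: (pos[c.u], c.u, pos[c.v], c.v))
    return claims


def test_claim(
    claim: IndependenceClaim,
    data: pd.DataFrame,
    tree: PhyloTree,
    model: str = "BM",
) -> IndependenceClaim:
    """Fit the claim's PGLS regression and record the independence p-value.

    The designated response is regressed on its conditioning set plus the
    other vertex of the pair; the claim p is the two-sided p-value of that
    last coefficient under the given evolutionary model.
    """
    for col in (claim.u, claim.v, *claim.conditioning):
        if col not in data.columns:
            raise ValidationError(f"claim variable {col!r} missing from data")
    order = tuple(data.index.astype(str))
    y = data[claim.response].to_numpy(float)
    other = claim.other
    cols = [data[c].to_numpy(float) for c in claim.conditioning] + [data[other].to_numpy(float)]
    X = np.column_stack([np.ones(len(y))] + cols)
    fit = _pgls.fit_pgls(
        y, X, tree, model, tip_order=order,
        coef_names=("intercept", *claim.conditioning, other),
    )
    claim.p = float(fit.p[-1])
    claim.coefficient = float(fit.coef[-1])
    claim.model = model
    return claim


def fisher_c(pvalues) -> float:
    """Fisher's C = -2 * sum(ln p_i) over the basis-set claims."""
    p = np.asarray(list(pvalues), float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("claim p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


@dataclass
class PSEMFit:
    """A fitted piecewise SEM: equations, claims and goodness of fit."""

    model: PathModel
    equations: dict
    claims: list
    c_statistic: float
    df: int
    p: float
    k_claims: int
    n_params: int  # K: intercepts + slopes + one per correlated-error pair
    aic: float
    passed: bool
    correlated_error_tests: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "name": self.model.name,
            "edges": [list(e) for e in self.model.edges],
            "correlated_errors": [sorted(p) for p in self.model.correlated_errors],
            "equations": self.equations,
            "claims": [
                {
                    "u": c.u, "v": c.v, "conditioning": list(c.conditioning),
                    "response": c.response, "p": c.p, "model": c.model,
                }
                for c in self.claims
            ],
            "C": self.c_statistic,
            "df": self.df,
            "p": self.p,
            "K": self.n_params,
            "AIC": self.aic,
            "passed": self.passed,
            "correlated_error_tests": self.correlated_error_tests,
        }


def _equation_residual(v: str, model: PathModel, data: pd.DataFrame, fits: dict) -> np.ndarray:
    if v in fits:
        return fits[v].residuals
    x = data[v].to_numpy(float)
    return x - x.mean()


def fit_psem(
    model: PathModel,
    data: pd.DataFrame,
    tree: PhyloTree,
    evolutionary_models=("BM", "PL", "OU"),
    alpha: float = 0.05,
) -> PSEMFit:
    """Fit every structural equation by PGLS and run the d-separation test.

    Per equation the evolutionary model is chosen by AIC among
    ``evolutionary_models`` (pass a single tag to fix it).  Each basis-set
    claim is then tested under its response equation's selected model.
    Standardized coefficients are ``b * sd(x) / sd(y)`` with raw sample
    standard deviations; R-squared is the squared Pearson correlation of
    fitted and observed values.  ``K`` counts intercepts, slopes and one
    parameter per correlated-error pair; ``AIC = C + 2K``.
    """
    if isinstance(evolutionary_models, str):
        evolutionary_models = (evolutionary_models,)
    order = tuple(data.index.astype(str))
    tree.check_species(order)
    fits: dict[str, _pgls.PGLSFit] = {}
    equations: dict[str, dict] = {}
    n_params = 0
    for v in model.endogenous():
        parents = sorted(model.parents(v))
        y = data[v].to_numpy(float)
        X = np.column_stack([np.ones(len(y))] + [data[p].to_numpy(float) for p in parents])
        names = ("intercept", *parents)
        try:
            if len(evolutionary_models) == 1:
                fit = _pgls.fit_pgls(
                    y, X, tree, evolutionary_models[0], tip_order=order, coef_names=names
                )
            else:
                fit, _ = _pgls.compare_evolutionary_models(
                    y, X, tree, evolutionary_models, tip_order=order, coef_names=names
                )
        except Exception as exc:
            raise ValidationError(f"equation for {v!r} failed to fit: {exc}") from exc
        fits[v] = fit
        sd_y = float(np.std(y, ddof=1))
        std_coef = {
            p: float(fit.coef[i + 1]) * float(np.std(data[p], ddof=1)) / sd_y
            for i, p in enumerate(parents)
        }
        obs_fit_corr = np.corrcoef(fit.fitted, y)[0, 1]
        equations[v] = {
            "predictors": parents,
            "model": fit.model,
            "coefficients": {nm: float(b) for nm, b in zip(names, fit.coef)},
            "se": {nm: float(s) for nm, s in zip(names, fit.se)},
            "p": {nm: float(p) for nm, p in zip(names, fit.p)},
            "standardized": std_coef,
            "r2": float(obs_fit_corr**2),
            "parameter": fit.parameter,
        }
        n_params += 1 + len(parents)
    n_params += len(model.correlated_errors)

    claims = basis_set(model)
    for c in claims:
        eq_model = fits[c.response].model if c.response in fits else "BM"
        if eq_model not in ("BM", "PL", "OU"):
            eq_model = "BM"
        test_claim(c, data, tree, model=eq_model)
    k = len(claims)
    # clamp underflowed claim p-values; C is effectively infinite there anyway
    c_stat = fisher_c([max(c.p, 1e-300) for c in claims]) if claims else 0.0
    df = 2 * k
    p = float(stats.chi2.sf(c_stat, df)) if k else 1.0
    passed = p > alpha and all(c.p >= alpha for c in claims)

    ce_tests = []
    for pair in model.correlated_errors:
        a, b = sorted(pair)
        ra = _equation_residual(a, model, data, fits)
        rb = _equation_residual(b, model, data, fits)
        r = float(np.corrcoef(ra, rb)[0, 1])
        n = len(ra)
        dfree = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = r * np.sqrt(dfree / max(1e-300, 1.0 - r**2))
        pval = float(2.0 * stats.t.sf(abs(tval), dfree))
        ce_tests.append({"pair": [a, b], "r": r, "p": pval})

    return PSEMFit(
        model=model,
        equations=equations,
        claims=claims,
        c_statistic=c_stat,
        df=df,
        p=p,
        k_claims=k,
        n_params=n_params,
        aic=c_stat + 2 * n_params,
        passed=passed,
        correlated_error_tests=ce_tests,
    )


# ----------------------------------------------------------------------
# Candidate-model family


def enumerate_candidate_models(tags: dict | None = None) -> list[PathModel]:
    """Built-in candidate family over (PLa, tube, stigma, upper, lower).

    The predictor PLa sends direct edges to every non-empty subset of the
    three functional modules (accessibility = tube, efficiency = stigma,
    attractiveness = upper lip; the lower lip is attached to the upper by a
    fixed correlated error).  These are crossed with the inter-module
    cascade toggles tube->stigma, stigma->upper and tube->upper, and
    filtered to DAGs in which every module is reachable from PLa.  The
    correlated errors tube~~stigma and upper~~lower are fixed, except that
    tube~~stigma is dropped from models containing a directed tube->stigma
    edge (an edge and a correlated error may not share a pair).
    """
    tags = dict(tags or DEFAULT_TAGS)
    module_entry = {"accessibility": "tube", "efficiency": "stigma", "attractiveness": "upper"}
    modules = tuple(module_entry)
    family: list[PathModel] = []
    cascades = (("tube", "stigma"), ("stigma", "upper"), ("tube", "upper"))
    for mask in range(1, 8):
        direct = [modules[i] for i in range(3) if mask >> i & 1]
        for cmask in range(8):
            casc = [cascades[i] for i in range(3) if cmask >> i & 1]
            edges = [("PLa", module_entry[m]) for m in direct] + casc
            g = nx.DiGraph(edges)
            g.add_nodes_from(module_entry.values())
            reachable = nx.descendants(g, "PLa")
            if not all(module_entry[m] in reachable for m in modules):
                continue
            ces = [("upper", "lower")]
            if ("tube", "stigma") not in edges:
                ces.append(("tube", "stigma"))
            name = "PLa>" + "+".join(module_entry[m] for m in direct)
            if casc:
                name += "|" + ",".join(f"{a}>{b}" for a, b in casc)
            family.append(
                build_path_model(
                    edges, ces, tags=tags,
                    vertices=("PLa", "tube", "stigma", "upper", "lower"),
                    name=name,
                )
            )
    if not family:
        raise ValidationError("candidate family is empty")
    return family


def load_model_family(path: str | Path, tags: dict | None = None) -> list[PathModel]:
    """Read a user-supplied model family from a plain-text file.

    Models are blocks separated by blank lines.  Within a block,
    ``A -> B`` declares a directed edge, ``A ~~ B`` a correlated error,
    ``# name: <label>`` names the model and other ``#`` lines are comments.
    """
    text = Path(path).read_text()
    blocks = [b for b in text.split("\n\n") if b.strip()]
    family = []
    for i, block in enumerate(blocks):
        edges, ces, name = [], [], f"model_{i + 1}"
        for line in block.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# name:"):
                    name = line.split(":", 1)[1].strip()
                continue
            if "->" in line:
                a, b = (s.strip() for s in line.split("->"))
                edges.append((a, b))
            elif "~~" in line:
                a, b = (s.strip() for s in line.split("~~"))
                ces.append((a, b))
            else:
                raise ValidationError(f"unparseable path-model line: {line!r}")
        family.append(build_path_model(edges, ces, tags=tags, name=name))
    if not family:
        raise ValidationError(f"no models found in {path}")
    return family


def select_best(fits: list[PSEMFit]) -> tuple[PSEMFit | None, pd.DataFrame]:
    """Rank fitted candidate models and return the best admissible one.

    Admissible fits have overall p > 0.05 and no individually significant
    claim; among them the minimum-AIC fit wins, ties broken by fewer
    parameters then by position in the candidate list.  When nothing is
    admissible the best fit is None and the ranking table is still
    returned.
    """
    if not fits:
        raise ValidationError("select_best needs at least one fitted model")
    rows = []
    for i, f in enumerate(fits):
        rows.append(
            {
                "name": f.model.name or f"model_{i + 1}",
                "C": f.c_statistic,
                "df": f.df,
                "p": f.p,
                "K": f.n_params,
                "AIC": f.aic,
                "passed": f.passed,
            }
        )
    table = pd.DataFrame(rows)
    admissible = [(i, f) for i, f in enumerate(fits) if f.passed]
    if not admissible:
        table["selected"] = False
        return None, table
    best_i, best = min(admissible, key=lambda t: (t[1].aic, t[1].n_params, t[0]))
    table["selected"] = [i == best_i for i in range(len(fits))]
    return best, table
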