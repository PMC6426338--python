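"""Piecewise structural equation modeling on pair-level change data.

The causal model is a DAG over the four standardized changes: forest change
(dF) is exogenous; albedo change responds to forest change; evapotranspiration
change responds to forest and albedo change; and LST change responds to all
three.  Each endogenous variable gets its own GLS regression (piecewise
fitting), with spatial residual correlation anchored at the focal cell of
each pair.  Standardized coefficients — raw slope × SD(predictor)/SD(response)
on the analysis subset — make links comparable across variables, and the
effect of forest change on LST decomposes exactly into the direct link plus
products of standardized coefficients along the mediating pathways.

Pruned models (with links removed) are testable: the d-separation basis of
the pruned DAG yields one conditional-independence claim per missing link,
each tested by regression; Fisher's C = −2·Σ ln pᵢ is chi-squared with 2k
degrees of freedom when the model is right.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gls import (
    INDEPENDENCE,
    CorrelationStructure,
    ModelFit,
    fit_gls,
)

__all__ = [
    "PathModelSpec",
    "FittedPathModel",
    "EffectsDecomposition",
    "DEFAULT_SPEC",
    "fit_path_model",
    "standardize_coefficient",
    "effects_decomposition",
    "unstandardized_effect",
    "dsep_basis",
    "dsep_tests",
    "fishers_c",
    "r_squared",
]


@dataclass(frozen=True)
class PathModelSpec:
    """A recursive path model: one equation per endogenous variable.

    ``equations`` maps response → tuple of predictors.  The implied directed
    graph must be acyclic and every non-exogenous variable must have exactly
    one equation.
    """

    equations: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("equations do not form a DAG")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for resp, preds in self.equations.items():
            g.add_node(resp)
            for p in preds:
                g.add_edge(p, resp)
        return g

    @property
    def variables(self) -> list[str]:
        g = self.graph()
        return sorted(g.nodes)

    @property
    def exogenous(self) -> list[str]:
        return sorted(v for v in self.variables if v not in self.equations)

    def links(self) -> list[tuple[str, str]]:
        return [(p, resp) for resp, preds in self.equations.items() for p in preds]

    def drop_link(self, frm: str, to: str) -> "PathModelSpec":
        if to not in self.equations or frm not in self.equations[to]:
            raise KeyError(f"no link {frm} -> {to}")
        eqs = {r: tuple(p for p in ps if not (r == to and p == frm)) for r, ps in self.equations.items()}
        return PathModelSpec(eqs)

    @classmethod
    def from_text(cls, text: str) -> "PathModelSpec":
        """Parse one equation per line, e.g. ``dLST ~ dF + dAlbedo + dET``."""
        eqs = {}
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            resp, rhs = (s.strip() for s in line.split("~"))
            eqs[resp] = tuple(s.strip() for s in rhs.split("+"))
        return cls(eqs)

    def to_text(self) -> str:
        return "\n".join(f"{r} ~ {' + '.join(ps)}" for r, ps in self.equations.items())


#: the standard forest → albedo/ET → LST causal structure
DEFAULT_SPEC = PathModelSpec(
    {
        "dAlbedo": ("dF",),
        "dET": ("dF", "dAlbedo"),
        "dLST": ("dF", "dAlbedo", "dET"),
    }
)


def standardize_coefficient(raw: float, sd_predictor: float, sd_response: float) -> float:
    """Raw slope rescaled to SD units: raw × SD(predictor)/SD(response)."""
    if sd_predictor <= 0 or sd_response <= 0:
        raise ValueError("standard deviations must be positive")
    return raw * sd_predictor / sd_response


def r_squared(fit: ModelFit, y: np.ndarray | None = None) -> float:
    """Coefficient of determination, 1 − RSS/TSS on raw residuals."""
    resid = fit.residuals
    obs = fit.fitted + resid if y is None else np.asarray(y, dtype=float)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss <= 0:
        raise ValueError("zero total sum of squares")
    return 1.0 - float(np.sum(resid**2)) / tss


def _corr_r2(fit: ModelFit) -> float:
    """Alternative R²: squared fitted–observed correlation."""
    obs = fit.fitted + fit.residuals
    if np.std(fit.fitted) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(fit.fitted, obs)[0, 1] ** 2)


@dataclass
class FittedPathModel:
    """Component fits plus raw/standardized coefficients per directed link."""

    spec: PathModelSpec
    component_fits: dict  # response -> ModelFit
    raw: dict  # (from, to) -> raw coefficient
    standardized: dict  # (from, to) -> standardized coefficient
    p_values: dict  # (from, to) -> p
    r2: dict  # response -> R² (1 − RSS/TSS)
    r2_corr: dict  # response -> squared fitted-observed correlation
    sds: dict  # variable -> sample SD on the analysis subset
    structure: CorrelationStructure
    n: int

    def link_table(self) -> pd.DataFrame:
        rows = [
            {
                "from": f,
                "to": t,
                "raw": self.raw[(f, t)],
                "standardized": self.standardized[(f, t)],
                "p": self.p_values[(f, t)],
                "significant": self.p_values[(f, t)] <= 0.05,
            }
            for f, t in self.spec.links()
        ]
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "links": self.link_table().to_dict(orient="records"),
            "r2": self.r2,
            "r2_corr": self.r2_corr,
            "sds": self.sds,
            "n": self.n,
            "structure": {"family": self.structure.family, "range": self.structure.range},
            "decomposition": effects_decomposition(self).as_dict(),
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _complete_subset(pairs: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    cols = [f"{v}_std" for v in variables]
    return pairs.dropna(subset=cols)


def fit_path_model(
    pairs: pd.DataFrame,
    spec: PathModelSpec = DEFAULT_SPEC,
    structure: CorrelationStructure = CorrelationStructure("rational_quadratic"),
    *,
    method: str = "REML",
    min_n: int = 30,
) -> FittedPathModel:
    """Fit every component equation by GLS on the complete-case pair subset.

    Only pairs with valid standardized changes for all model variables enter
    (the path-analysis subset); sample SDs for standardization are taken on
    that same subset.  The spatial structure is anchored at each pair's focal
    cell coordinates.  The rational quadratic family is the default
    structure, being the top-ranked choice in most paired-model selections.

    Distance-based correlation families admit no zero inter-observation
    distances (a no-nugget spatial model cannot describe two unequal
    observations at one location, and the likelihood degenerates toward
    compound symmetry).  When the structure has a range and several pairs
    share a focal cell — one strong-change cell selected by overlapping
    windows — only the first pair per focal location is kept, with a warning.
    """
    data = _complete_subset(pairs, spec.variables)
    if structure.has_range:
        unique = data.drop_duplicates(subset=["focal_lon", "focal_lat"], keep="first")
        if len(unique) < len(data):
            warnings.warn(
                f"dropped {len(data) - len(unique)} pairs sharing focal-cell "
                "coordinates: spatial correlation structures require distinct "
                "observation locations"
            )
            data = unique
    n = len(data)
    if n < min_n:
        raise ValueError(f"need at least {min_n} complete pairs; got {n}")
    coords = data[["focal_lon", "focal_lat"]].to_numpy()
    sds = {v: float(data[f"{v}_std"].std(ddof=1)) for v in spec.variables}

    fits, raw, std, pvals, r2, r2c = {}, {}, {}, {}, {}, {}
    for resp, preds in spec.equations.items():
        y = data[f"{resp}_std"].to_numpy()
        X = np.column_stack([np.ones(n)] + [data[f"{p}_std"].to_numpy() for p in preds])
        fit = fit_gls(y, X, coords, structure, method=method, names=["intercept", *preds])
        fits[resp] = fit
        for p in preds:
            raw[(p, resp)] = fit.coef(p)
            std[(p, resp)] = standardize_coefficient(fit.coef(p), sds[p], sds[resp])
            pvals[(p, resp)] = fit.p_value(p)
        r2[resp] = r_squared(fit)
        r2c[resp] = _corr_r2(fit)

    fitted_structure = next(iter(fits.values())).structure
    return FittedPathModel(
        spec=spec,
        component_fits=fits,
        raw=raw,
        standardized=std,
        p_values=pvals,
        r2=r2,
        r2_corr=r2c,
        sds=sds,
        structure=fitted_structure,
        n=n,
    )


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectsDecomposition:
    """Direct, per-pathway indirect, and total standardized effects of dF on dLST."""

    direct: float
    indirect: dict  # pathway tuple -> product of standardized coefficients
    total: float

    @property
    def indirect_sum(self) -> float:
        return float(sum(self.indirect.values()))

    def as_dict(self) -> dict:
        return {
            "direct": self.direct,
            "indirect": {" -> ".join(path): v for path, v in self.indirect.items()},
            "indirect_sum": self.indirect_sum,
            "total": self.total,
        }


def effects_decomposition(
    model: "FittedPathModel | Mapping[tuple[str, str], float]",
    source: str = "dF",
    target: str = "dLST",
    spec: PathModelSpec = DEFAULT_SPEC,
) -> EffectsDecomposition:
    """Decompose the standardized effect of ``source`` on ``target``.

    The direct effect is the standardized coefficient of the direct link;
    each indirect effect is the product of standardized coefficients along
    one directed pathway through the mediators; the total is their sum —
    an exact identity, not an estimate.  Accepts a fitted model or a plain
    ``{(from, to): coefficient}`` mapping.
    """
    if isinstance(model, FittedPathModel):
        coeffs = model.standardized
        graph = model.spec.graph()
    else:
        coeffs = dict(model)
        graph = spec.graph()
    for edge in coeffs:
        if edge not in graph.edges:
            graph.add_edge(*edge)
    paths = list(nx.all_simple_paths(graph, source, target))
    direct = float(coeffs.get((source, target), 0.0))
    indirect = {}
    for path in paths:
        if len(path) == 2:
            continue
        prod = 1.0
        missing = False
        for a, b in zip(path[:-1], path[1:]):
            if (a, b) not in coeffs:
                missing = True
                break
            prod *= coeffs[(a, b)]
        if missing:
            raise KeyError(f"missing link coefficient along pathway {path}")
        indirect[tuple(path)] = float(prod)
    total = direct + sum(indirect.values())
    return EffectsDecomposition(direct=direct, indirect=indirect, total=float(total))


def unstandardized_effect(
    total_std: float, sd_dF: float, sd_dLST: float, delta_in_sd_units: float = 1.0
) -> float:
    """LST change (°C) for a forest-cover change of ``delta`` SDs of ΔF.

    A one-SD increase in forest change moves LST by ``total_std`` SDs of
    ΔLST, i.e. ``total_std × sd_dLST`` degrees; the sign follows the total
    effect (negative total → cooling for forest gain).
    """
    if sd_dF <= 0 or sd_dLST <= 0:
        raise ValueError("standard deviations must be positive")
    return float(total_std * sd_dLST * delta_in_sd_units)


# ---------------------------------------------------------------------------
# d-separation and Fisher's C
# ---------------------------------------------------------------------------

def dsep_basis(spec: PathModelSpec) -> list[tuple[str, str, tuple[str, ...]]]:
    """Basis set of d-separation claims for a (possibly pruned) DAG.

    For each non-adjacent ordered pair (x, y) with x preceding y in the
    causal order, the claim is y ⟂ x given the union of both variables'
    parents.  Ordering is deterministic: topological generations refined
    alphabetically.  A saturated model has an empty basis and admits no
    global test.
    """
    g = spec.graph()
    order: list[str] = []
    for gen in nx.topological_generations(g):
        order.extend(sorted(gen))
    rank = {v: i for i, v in enumerate(order)}
    claims = []
    for i, x in enumerate(order):
        for y in order[i + 1 :]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            cond = sorted((set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y})
            claims.append((x, y, tuple(cond)))
    claims.sort(key=lambda c: (rank[c[1]], rank[c[0]]))
    return claims


def dsep_tests(
    pairs: pd.DataFrame,
    spec: PathModelSpec,
    structure: CorrelationStructure = INDEPENDENCE,
    *,
    method: str = "REML",
) -> list[dict]:
    """Test every basis claim by regression; returns one record per claim.

    The claim x ⟂ y | Z is tested by regressing y on Z plus x with the same
    GLS structure used for the component models and reading the p-value of
    the added predictor x (t reference with n − k residual df).
    """
    claims = dsep_basis(spec)
    data = _complete_subset(pairs, spec.variables)
    coords = data[["focal_lon", "focal_lat"]].to_numpy()
    out = []
    for x, y, cond in claims:
        preds = [*cond, x]
        X = np.column_stack(
            [np.ones(len(data))] + [data[f"{p}_std"].to_numpy() for p in preds]
        )
        fit = fit_gls(
            data[f"{y}_std"].to_numpy(),
            X,
            coords,
            structure,
            method=method,
            names=["intercept", *preds],
        )
        out.append({"x": x, "y": y, "conditioning": cond, "p": fit.p_value(x)})
    return out


def fishers_c(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p-values: (C, df, global p).

    C = −2·Σ ln pᵢ is chi-squared with 2k df under the model; a significant
    C (small global p) indicates the removed links were needed.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one claim p-value")
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    df = 2 * ps.size
    if np.any(ps == 0):
        import warnings

        warnings.warn("claim p-value of 0: Fisher's C is infinite")
        return float("inf"), df, 0.0
    C = -2.0 * float(np.sum(np.log(ps)))
    return C, df, float(stats.chi2.sf(C, df))
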