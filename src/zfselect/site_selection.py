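"""Site-model tests of positive selection on zinc-finger codon alignments.

Workflow: stack decomposed arrays unit-by-unit into a codon alignment (the
84-nt periodicity makes column homology explicit, so no general-purpose MSA
is needed), build a neighbor-joining tree from codon p-distances, optimize
branch lengths under M0, then — holding branch lengths fixed — fit the site
models M0, M1a (nearly neutral), M2a (selection), M7 (beta) and M8
(beta & omega), compare the nested pairs by likelihood-ratio test against
chi-square with 2 df, and classify sites by Bayes Empirical Bayes.

The M1a/M2a and M7/M8 nulls sit on the boundary of the alternative, which
makes the chi-square reference conservative; this is the conventional
treatment and is documented rather than corrected.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .codon_model import (
    MISSING,
    CodonLikelihood,
    codons_to_codes,
    mixture_scale_factor,
    STOP_CODONS,
)
from .trees import Tree, neighbor_joining
from .zf_decompose import ZFArray

__all__ = [
    "CodonAlignment",
    "SiteModelSpec",
    "FitResult",
    "LRTResult",
    "SiteClassification",
    "build_codon_alignment",
    "codon_p_distances",
    "nj_tree",
    "optimize_branch_lengths",
    "class_distribution",
    "fit_site_model",
    "lrt",
    "beb_classify",
    "lrt_table",
]

NESTED_PAIRS = {("M1a", "M2a"), ("M7", "M8"), ("M0", "M1a")}


@dataclass
class CodonAlignment:
    """Unit-indexed codon alignment over the 61 sense-codon states."""

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_sites); MISSING for absent trailing units
    site_to_unit_position: list[tuple[int, int]]  # (unit index, codon offset 1..28)
    helix_positions: list[int | None] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]


def build_codon_alignment(arrays: list[ZFArray], include_first_finger: bool = False,
                          strict_equal_length: bool = False) -> CodonAlignment:
    """Stack arrays unit-by-unit from the array start into codon columns.

    Arrays with fewer units than the longest carry missing-data states in
    the absent trailing units (``strict_equal_length=True`` refuses unequal
    arrays instead, matching an equal-repeat-number study design).  The
    conserved leading finger is excluded unless requested.  Any stop codon
    among observed states is a hard error naming the record: pseudogenes
    must be routed to the disruption scan, not here.
    """
    if len(arrays) < 3:
        raise ValueError("codon alignment needs >= 3 arrays")
    n_units = [a.n_units for a in arrays]
    if strict_equal_length and len(set(n_units)) != 1:
        raise ValueError(f"unequal unit counts {sorted(set(n_units))} in strict mode")
    max_units = max(n_units)
    taxa = [a.record_id for a in arrays]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate record ids among arrays")

    site_map: list[tuple[int, int]] = []
    if include_first_finger:
        site_map += [(0, k + 1) for k in range(23)]
    for u in range(1, max_units + 1):
        site_map += [(u, k + 1) for k in range(28)]

    rows = []
    for arr in arrays:
        codons: list[str | None] = []
        if include_first_finger:
            lead = arr.leading_finger_nt
            codons += [lead[3 * k : 3 * k + 3] or None for k in range(23)]
        for u in range(max_units):
            if u < arr.n_units:
                nt = arr.units[u].nt
                codons += [nt[3 * k : 3 * k + 3] for k in range(28)]
            else:
                codons += [None] * 28
        for pos, codon in enumerate(codons):
            if codon in STOP_CODONS:
                unit, off = site_map[pos]
                raise ValueError(
                    f"stop codon in {arr.record_id} at unit {unit} codon {off}; "
                    "exclude pseudogenes upstream"
                )
        rows.append(codons_to_codes(codons))
    codes = np.vstack(rows)

    # helix label per column from the modal His1 anchor at that unit slot
    helix: list[int | None] = []
    his1_by_unit: dict[int, int] = {}
    for u in range(1, max_units + 1):
        anchors = [a.units[u - 1].anchors[2] for a in arrays if a.n_units >= u]
        if anchors:
            his1_by_unit[u] = Counter(anchors).most_common(1)[0][0]
    for unit, off in site_map:
        h1 = his1_by_unit.get(unit)
        if h1 is None:
            helix.append(None)
        else:
            k = off - h1 + 7 if off - h1 + 7 >= 1 else off - h1 + 6
            # labels are only meaningful around the recognition helix
            helix.append(k if -9 <= k <= 6 else None)
    return CodonAlignment(taxa=taxa, codes=codes, site_to_unit_position=site_map,
                          helix_positions=helix)


def codon_p_distances(aln: CodonAlignment) -> np.ndarray:
    """Pairwise fraction of differing codon sites over both-observed columns."""
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (aln.codes[i] != MISSING) & (aln.codes[j] != MISSING)
            if not both.any():
                raise ValueError(
                    f"no shared observed sites between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            d[i, j] = d[j, i] = np.mean(aln.codes[i][both] != aln.codes[j][both])
    return d


def nj_tree(aln: CodonAlignment) -> Tree:
    return neighbor_joining(aln.taxa, codon_p_distances(aln))


def optimize_branch_lengths(cl: CodonLikelihood, kappa: float, omega: float,
                            sweeps: int = 2, max_len: float = 20.0) -> np.ndarray:
    """Coordinate-wise ML branch lengths under M0 (Brent per branch)."""
    idx = cl.index
    for _ in range(sweeps):
        for nid in range(idx.n_nodes):
            if idx.parent[nid] < 0:
                continue

            def neg(t, nid=nid):
                idx.lengths[nid] = t
                return -cl.loglik(kappa, [1.0], [omega])

            res = optimize.minimize_scalar(
                neg, bounds=(1e-8, max_len), method="bounded",
                options={"xatol": 1e-6},
            )
            idx.lengths[nid] = res.x
    return idx.lengths.copy()


# ---------------------------------------------------------------------------
# site models


@dataclass(frozen=True)
class SiteModelSpec:
    model: str
    n_categories: int = 10  # beta discretization for M7/M8

    def __post_init__(self) -> None:
        if self.model not in ("M0", "M1a", "M2a", "M7", "M8"):
            raise ValueError(f"unknown site model {self.model!r}")


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    lnL: float
    kappa: float
    weights: np.ndarray
    omegas: np.ndarray
    converged: bool
    n_categories: int = 10


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    two_delta_l: float
    df: int
    p_value: float

    @property
    def stars(self) -> str:
        return "**" if self.p_value < 0.01 else "*" if self.p_value < 0.05 else ""


@dataclass
class SiteClassification:
    model: str
    p_positive: np.ndarray        # per-site P(omega > 1)
    post_mean_omega: np.ndarray
    threshold: float
    site_to_unit_position: list[tuple[int, int]]
    helix_positions: list[int | None]

    @property
    def flagged(self) -> np.ndarray:
        return self.p_positive > self.threshold

    def flagged_helix_positions(self) -> list[int]:
        return sorted(
            {
                self.helix_positions[i]
                for i in np.where(self.flagged)[0]
                if self.helix_positions[i] is not None
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.p_positive)):
            unit, off = self.site_to_unit_position[i]
            rows.append(
                {
                    "site": i + 1,
                    "unit": unit,
                    "codon_offset": off,
                    "helix_position": self.helix_positions[i],
                    "p_positive": self.p_positive[i],
                    "post_mean_omega": self.post_mean_omega[i],
                    "flagged": bool(self.flagged[i]),
                }
            )
        return pd.DataFrame(rows)


_BOUNDS = {
    "kappa": (0.05, 50.0),
    "omega0": (1e-4, 1.0),
    "omega_pos": (1.0, 50.0),
    "prop": (0.0, 1.0),
    "beta": (0.005, 99.0),
    "omega_m0": (1e-4, 50.0),
}


def _squash(x, lo, hi):
    return lo + (hi - lo) * expit(x)


def _unsquash(v, lo, hi):
    v = min(max(v, lo + 1e-9 * (hi - lo)), hi - 1e-9 * (hi - lo))
    return logit((v - lo) / (hi - lo))


_PARAM_KINDS = {
    "M0": [("omega", "omega_m0")],
    "M1a": [("p0", "prop"), ("omega0", "omega0")],
    "M2a": [("p0", "prop"), ("p1c", "prop"), ("omega0", "omega0"),
            ("omega2", "omega_pos")],
    "M7": [("p", "beta"), ("q", "beta")],
    "M8": [("p0", "prop"), ("p", "beta"), ("q", "beta"), ("omega_s", "omega_pos")],
}
# p1c is the stick-breaking fraction: p1 = (1 - p0) * p1c

_DEFAULT_START = {
    "M0": {"omega": 0.5},
    "M1a": {"p0": 0.7, "omega0": 0.2},
    "M2a": {"p0": 0.6, "p1c": 0.75, "omega0": 0.2, "omega2": 3.0},
    "M7": {"p": 0.5, "q": 1.5},
    "M8": {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 3.0},
}


def _beta_category_means(p: float, q: float, k: int) -> np.ndarray:
    """K equal-probability beta categories by quantile midpoints."""
    return stats.beta.ppf((2 * np.arange(k) + 1) / (2 * k), p, q)


def class_distribution(model: str, params: dict[str, float], n_categories: int = 10):
    """(weights, omegas) of the site-class mixture a model implies."""
    if model == "M0":
        return np.array([1.0]), np.array([params["omega"]])
    if model == "M1a":
        p0 = params["p0"]
        return np.array([p0, 1 - p0]), np.array([params["omega0"], 1.0])
    if model == "M2a":
        p0 = params["p0"]
        p1 = params["p1"] if "p1" in params else (1 - p0) * params["p1c"]
        return (
            np.array([p0, p1, 1 - p0 - p1]),
            np.array([params["omega0"], 1.0, params["omega2"]]),
        )
    if model == "M7":
        w = np.full(n_categories, 1 / n_categories)
        return w, _beta_category_means(params["p"], params["q"], n_categories)
    if model == "M8":
        p0 = params["p0"]
        w = np.concatenate([np.full(n_categories, p0 / n_categories), [1 - p0]])
        om = np.concatenate(
            [_beta_category_means(params["p"], params["q"], n_categories),
             [params["omega_s"]]]
        )
        return w, om
    raise ValueError(f"unknown site model {model!r}")


def _natural_params(model: str, params: dict[str, float]) -> dict[str, float]:
    """Resolve stick-breaking p1c into the reported p1 for M2a."""
    out = dict(params)
    if model == "M2a" and "p1c" in out:
        out["p1"] = (1 - out["p0"]) * out.pop("p1c")
    return out


def _embedded_alt_point(null_fit: FitResult, alt_model: str) -> dict[str, float]:
    """The alternative-model point that reproduces the null fit exactly."""
    p = null_fit.params
    if (null_fit.model, alt_model) == ("M1a", "M2a"):
        return {"p0": p["p0"], "p1": 1 - p["p0"], "omega0": p["omega0"],
                "omega2": 2.0}
    if (null_fit.model, alt_model) == ("M7", "M8"):
        return {"p0": 1.0, "p": p["p"], "q": p["q"], "omega_s": 2.0}
    raise ValueError(f"{null_fit.model} is not nested in {alt_model}")


def fit_site_model(aln: CodonAlignment, tree: Tree, spec: SiteModelSpec | str,
                   n_starts: int = 3, seed: int = 1, null_fit: FitResult | None = None,
                   kappa_start: float = 2.0, maxfev: int | None = None) -> FitResult:
    """Maximum-likelihood fit of one site model with branch lengths fixed.

    Derivative-free (Nelder–Mead) multi-start optimization over the model's
    free parameters plus kappa; box constraints are enforced by sigmoid
    transforms and proportions by stick-breaking.  When ``null_fit`` is the
    fit of the nested null, its embedded point in the alternative space is
    evaluated and returned if the search never beats it, so
    lnL(alt) >= lnL(null) holds exactly.
    """
    if isinstance(spec, str):
        spec = SiteModelSpec(spec)
    model, K = spec.model, spec.n_categories
    cl = CodonLikelihood(aln.codes, tree, aln.taxa)
    kinds = _PARAM_KINDS[model]
    names = ["kappa"] + [n for n, _ in kinds]
    bounds = [_BOUNDS["kappa"]] + [_BOUNDS[k] for _, k in kinds]

    def unpack(x):
        return {n: _squash(v, *b) for n, v, b in zip(names, x, bounds)}

    def pack(params):
        return np.array([_unsquash(params[n], *b) for n, b in zip(names, bounds)])

    n_eval = 0

    def neg_loglik(x):
        nonlocal n_eval
        n_eval += 1
        p = unpack(x)
        try:
            w, om = class_distribution(model, p, K)
            return -cl.loglik(p["kappa"], w, om)
        except FloatingPointError:
            return 1e10

    start0 = {"kappa": kappa_start, **_DEFAULT_START[model]}
    starts = [pack(start0)]
    if null_fit is not None:
        near = dict(_embedded_alt_point(null_fit, model))
        if model == "M2a":
            p0 = min(near["p0"], 0.98)
            p1 = max(min(near["p1"], 0.98 - p0), 0.01)
            near = {"p0": p0, "p1c": p1 / (1 - p0), "omega0": near["omega0"],
                    "omega2": near["omega2"]}
        elif model == "M8":
            near["p0"] = min(near["p0"], 0.98)
        starts.insert(0, pack({"kappa": null_fit.kappa, **near}))
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(starts[0] + rng.normal(0, 0.75, size=len(names)))

    if maxfev is None:
        maxfev = 200 + 120 * len(names)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik, x0, method="Nelder-Mead",
            options={"fatol": 1e-6, "xatol": 1e-4, "maxfev": maxfev},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = _natural_params(model, unpack(best.x))
    lnL = -best.fun
    converged = bool(best.success)
    kappa = params.pop("kappa")

    if null_fit is not None and lnL < null_fit.lnL:
        # boundary case: the alternative's maximum is the embedded null
        params = _embedded_alt_point(null_fit, model)
        kappa = null_fit.kappa
        lnL = null_fit.lnL
        converged = null_fit.converged
    w, om = class_distribution(model, params, K)
    return FitResult(model=model, params=params, lnL=lnL, kappa=kappa,
                     weights=w, omegas=om, converged=converged, n_categories=K)


def lrt(null: FitResult, alt: FitResult, df: int = 2) -> LRTResult:
    """2*(lnL_alt - lnL_null) against chi-square (df=2 by convention)."""
    if (null.model, alt.model) not in NESTED_PAIRS:
        raise ValueError(f"{null.model} is not nested in {alt.model}")
    raw = 2 * (alt.lnL - null.lnL)
    if raw < -1e-6:
        raise ValueError(
            f"lnL({alt.model}) < lnL({null.model}); refit the alternative"
        )
    stat = max(raw, 0.0)
    return LRTResult(
        null_model=null.model, alt_model=alt.model, two_delta_l=stat, df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


def lrt_table(results: dict[str, dict[str, LRTResult]]) -> pd.DataFrame:
    """Per-species LRT table: one row per species, one column per model pair."""
    rows = []
    for species, tests in results.items():
        row = {"species": species}
        for key, r in tests.items():
            if r is None:
                row[f"2dl_{key}"] = None
                row[f"stars_{key}"] = "insufficient data"
            else:
                row[f"2dl_{key}"] = round(r.two_delta_l, 3)
                row[f"stars_{key}"] = r.stars
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayes Empirical Bayes


def _grid(n: int = 10) -> np.ndarray:
    return (np.arange(n) + 0.5) / n


def beb_classify(aln: CodonAlignment, tree: Tree, fit: FitResult,
                 threshold: float = 0.95, grid_points: int = 10) -> SiteClassification:
    """Bayes Empirical Bayes site classification under M2a or M8.

    Uniform prior grids (``grid_points`` per free proportion/omega dimension)
    over the model's class parameters; per-site class posteriors are averaged
    over the grid weighted by each grid point's data likelihood.  Branch
    lengths, kappa and (for M8) the beta shape parameters are held at their
    ML estimates.  Sites with P(omega > 1) above ``threshold`` are flagged
    and mapped to their zinc-finger helix positions.
    """
    if not fit.converged:
        raise ValueError("refusing BEB on a non-converged fit")
    if fit.model not in ("M2a", "M8"):
        raise ValueError(f"BEB requires an M2a or M8 fit, got {fit.model}")
    cl = CodonLikelihood(aln.codes, tree, aln.taxa)
    g = _grid(grid_points)
    # keep every grid omega on the fitted mixture's branch-length clock
    scale = mixture_scale_factor(cl.pi, fit.kappa, fit.omegas, fit.weights)

    if fit.model == "M2a":
        omega0_grid = g                                   # (0,1)
        omega2_grid = 1.0 + 10.0 * g                      # (1,11)
        all_omegas = np.concatenate([omega0_grid, [1.0], omega2_grid])
        logf = cl.class_site_logliks(fit.kappa, all_omegas, scale_factor=scale)
        f0, f1, f2 = logf[:grid_points], logf[grid_points], logf[grid_points + 1:]
        combos = []           # (w0, w1, w2, i_omega0, i_omega2)
        for p0 in g:
            for p1 in g:
                if p0 + p1 >= 1:
                    continue
                for i0 in range(grid_points):
                    for i2 in range(grid_points):
                        combos.append((p0, p1, 1 - p0 - p1, i0, i2))
        w = np.array([(c[0], c[1], c[2]) for c in combos])        # (G,3)
        i0 = np.array([c[3] for c in combos])
        i2 = np.array([c[4] for c in combos])
        logf_stack = np.stack([f0[i0], np.broadcast_to(f1, (len(combos), aln.n_sites)),
                               f2[i2]], axis=1)                    # (G,3,S)
        class_omegas = np.stack(
            [omega0_grid[i0], np.ones(len(combos)), omega2_grid[i2]], axis=1
        )                                                          # (G,3)
        positive_class = np.array([False, False, True])
    else:  # M8
        beta_omegas = _beta_category_means(fit.params["p"], fit.params["q"],
                                           fit.n_categories)
        omegas_s_grid = 1.0 + 10.0 * g
        all_omegas = np.concatenate([beta_omegas, omegas_s_grid])
        logf = cl.class_site_logliks(fit.kappa, all_omegas, scale_factor=scale)
        fbeta, fs = logf[: fit.n_categories], logf[fit.n_categories:]
        combos = [(p0, isel) for p0 in g for isel in range(grid_points)]
        w = np.array(
            [[p0 / fit.n_categories] * fit.n_categories + [1 - p0]
             for p0, _ in combos]
        )                                                          # (G,K+1)
        isel = np.array([c[1] for c in combos])
        logf_stack = np.concatenate(
            [np.broadcast_to(fbeta, (len(combos), fit.n_categories, aln.n_sites)),
             fs[isel][:, None, :]], axis=1)                        # (G,K+1,S)
        class_omegas = np.concatenate(
            [np.broadcast_to(beta_omegas, (len(combos), fit.n_categories)),
             omegas_s_grid[isel][:, None]], axis=1)
        positive_class = np.array([False] * fit.n_categories + [True])

    # per-site normalization keeps the exponentials in range; the shared
    # constant cancels from every posterior below
    c = logf_stack.max(axis=(0, 1))                                # (S,)
    fexp = np.exp(logf_stack - c[None, None, :])
    site_mix = np.einsum("gk,gks->gs", w, fexp)                    # (G,S)
    log_marginal = np.log(site_mix).sum(axis=1)                    # (G,)
    log_post_g = log_marginal - log_marginal.max()
    post_g = np.exp(log_post_g)
    post_g /= post_g.sum()

    class_post = w[:, :, None] * fexp / site_mix[:, None, :]       # (G,K,S)
    p_positive = np.einsum("g,gks->s", post_g, class_post[:, positive_class, :])
    mean_omega = np.einsum("g,gk,gks->s", post_g, class_omegas, class_post)

    return SiteClassification(
        model=fit.model,
        p_positive=p_positive,
        post_mean_omega=mean_omega,
        threshold=threshold,
        site_to_unit_position=aln.site_to_unit_position,
        helix_positions=aln.helix_positions,
    )
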