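"""Approximate Bayesian Computation for 3-population scenario choice.

Workflow (mirroring the rejection/regression ABC of DIYABC):

1. draw parameters from uniform priors (effective sizes, split times in
   generations, per-site mutation rate);
2. simulate a reference table of coalescent datasets under each scenario and
   reduce each to a fixed vector of summary statistics;
3. standardize, find the simulations closest (Euclidean) to the observed
   vector, and estimate posterior scenario probabilities by weighted
   multinomial logistic regression (Epanechnikov kernel weights), with
   confidence intervals from the regression's asymptotic variance;
4. for the selected scenario, estimate parameter posteriors by local-linear
   regression adjustment of the accepted draws (log scale), reported as
   median and 95% credible interval, with split times also converted to
   years via the generation time.

Summary statistics (fixed, documented order)
--------------------------------------------
Per group, in group order: number of haplotypes, number of segregating
sites, mean pairwise differences, private segregating sites (segregating in
the group, invariant in every other group).  Per group pair, in
lexicographic index order: mean within-pair pairwise differences (W, pooled
over the two groups), mean between-group pairwise differences (B), and
``FST = 1 - W/B`` clipped to [0, 1] (0 by convention when B = 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .coalsim import (
    SCENARIO_KINDS,
    SUDDEN_TRIFURCATION,
    Scenario,
    SimParams,
    simulate_matrix,
)
from .data_io import Alignment, SampleTable, usable_sites

logger = logging.getLogger(__name__)

PARAM_NAMES = ("ne1", "ne2", "ne3", "ne_anc", "t1", "t2", "mu")


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for the scenario parameters."""

    ne_bounds: tuple[float, float] = (10.0, 10_000.0)
    t_bounds: tuple[float, float] = (10.0, 10_000.0)
    mu_bounds: tuple[float, float] = (1e-8, 1e-6)
    mu_log_uniform: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.ne_bounds, self.t_bounds, self.mu_bounds):
            if not lo < hi:
                raise ValueError("prior bounds must satisfy lower < upper")


def sample_priors(
    spec: PriorSpec,
    kind: str,
    rng: np.random.Generator,
    populations: tuple[str, str, str] = ("P1", "P2", "P3"),
) -> tuple[Scenario, float]:
    """One prior draw: a concrete Scenario plus a mutation rate.

    Each of the three sampled populations and the ancestral population gets
    an independent Ne.  For the gradual scenarios (t1, t2) is a draw from
    the uniform prior conditioned on t1 < t2 (sorting two independent
    uniforms, which is that conditional distribution exactly).
    """
    ne = rng.uniform(*spec.ne_bounds, size=4)
    if kind == SUDDEN_TRIFURCATION:
        t1, t2 = float(rng.uniform(*spec.t_bounds)), None
    else:
        t1, t2 = np.sort(rng.uniform(*spec.t_bounds, size=2))
        t1, t2 = float(t1), float(t2)
    if spec.mu_log_uniform:
        mu = float(np.exp(rng.uniform(*np.log(spec.mu_bounds))))
    else:
        mu = float(rng.uniform(*spec.mu_bounds))
    scen = Scenario(kind, tuple(populations), tuple(ne[:3]), float(ne[3]), t1, t2)
    return scen, mu


# ---------------------------------------------------------------------------
# summary statistics


@dataclass(frozen=True)
class SummaryStatVector:
    values: np.ndarray
    names: tuple[str, ...]
    groups: tuple[str, ...]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def stat_names(groups: Sequence[str]) -> tuple[str, ...]:
    names = []
    for g in groups:
        names += [f"{g}_h", f"{g}_S", f"{g}_kbar", f"{g}_privS"]
    for i, j in combinations(range(len(groups)), 2):
        a, b = groups[i], groups[j]
        names += [f"{a}|{b}_W", f"{a}|{b}_B", f"{a}|{b}_FST"]
    return tuple(names)


def _stats_from_matrix(G: np.ndarray, sizes: Sequence[int],
                       groups: Sequence[str]) -> SummaryStatVector:
    """Summary statistics from an allele matrix (n_samples x variable sites).

    Rows are ordered group by group with the given sizes; invariant sites
    may be present or omitted without affecting any statistic.
    """
    sizes = list(sizes)
    if any(s < 2 for s in sizes):
        raise ValueError("every group needs n >= 2 for the summary statistics")
    edges = np.concatenate([[0], np.cumsum(sizes)])
    subs = [G[edges[i]: edges[i + 1]] for i in range(len(sizes))]
    s = G.shape[1]
    alleles = np.unique(G) if s else np.array([], dtype=G.dtype)
    # per-group per-allele column counts
    counts = [
        np.stack([(sub == a).sum(axis=0) for a in alleles])
        if s else np.zeros((0, 0), dtype=int)
        for sub in subs
    ]
    vals: list[float] = []
    within_sum = []
    mono = []
    for g, (sub, n, cnt) in enumerate(zip(subs, sizes, counts)):
        npairs = n * (n - 1) / 2.0
        if s:
            same = (cnt * (cnt - 1) // 2).sum(axis=0)
            diff_per_col = npairs - same
            seg = diff_per_col > 0
            mono.append(~seg)
            within = float(diff_per_col.sum())
            h = np.unique(sub, axis=0).shape[0]
        else:
            seg = np.zeros(0, dtype=bool)
            mono.append(seg)
            within = 0.0
            h = 1
        within_sum.append(within)
        vals += [float(h), float(seg.sum()), within / npairs, 0.0]
    # private segregating sites need all groups' monomorphism masks
    for g in range(len(sizes)):
        if s:
            others = np.ones(s, dtype=bool)
            for o in range(len(sizes)):
                if o != g:
                    others &= mono[o]
            seg_g = ~mono[g]
            vals[4 * g + 3] = float((seg_g & others).sum())
    for i, j in combinations(range(len(sizes)), 2):
        ni, nj = sizes[i], sizes[j]
        if s:
            cross = float((ni * nj - (counts[i] * counts[j]).sum(axis=0)).sum())
        else:
            cross = 0.0
        B = cross / (ni * nj)
        wpairs = ni * (ni - 1) / 2.0 + nj * (nj - 1) / 2.0
        W = (within_sum[i] + within_sum[j]) / wpairs
        fst = float(np.clip(1.0 - W / B, 0.0, 1.0)) if B > 0 else 0.0
        vals += [W, B, fst]
    return SummaryStatVector(np.asarray(vals, dtype=float),
                             stat_names(groups), tuple(groups))


def summary_statistics(
    aln: Alignment,
    samples: SampleTable,
    partition: str = "group",
    groups: Sequence[str] | None = None,
) -> SummaryStatVector:
    """Observed summary-statistic vector for >= 2 groups of an alignment.

    Computed on the complete-deletion usable sites of the alignment.
    """
    groups = list(groups) if groups is not None else samples.groups(partition)
    if len(groups) < 2:
        raise ValueError("summary statistics need >= 2 groups")
    mask = usable_sites(aln)
    ids, sizes = [], []
    for g in groups:
        gids = [s for s in samples.ids_for(partition, g) if s in aln.sample_ids]
        if len(gids) < 2:
            raise ValueError(f"group {g!r} has n < 2")
        ids += gids
        sizes.append(len(gids))
    G = aln.subset(ids).matrix[:, mask]
    return _stats_from_matrix(G, sizes, groups)


# ---------------------------------------------------------------------------
# reference table


@dataclass(frozen=True)
class ReferenceTable:
    """Rows of (scenario id, drawn parameters, summary statistics)."""

    frame: pd.DataFrame
    stat_names: tuple[str, ...]
    priors: PriorSpec
    sample_sizes: tuple[int, ...]
    L: int

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def stats(self) -> np.ndarray:
        return self.frame[list(self.stat_names)].to_numpy(dtype=float)

    def scenario_ids(self) -> np.ndarray:
        return self.frame["scenario"].to_numpy(dtype=int)

    @classmethod
    def concat(cls, tables: Sequence["ReferenceTable"]) -> "ReferenceTable":
        first = tables[0]
        frame = pd.concat([t.frame for t in tables], ignore_index=True)
        return cls(frame, first.stat_names, first.priors, first.sample_sizes,
                   first.L)

    def write(self, path) -> None:
        """TSV of rows plus a JSON sidecar recording priors and dimensions."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        meta = {
            "priors": asdict(self.priors),
            "sample_sizes": list(self.sample_sizes),
            "L": self.L,
            "n_rows": self.n_rows,
            "stat_names": list(self.stat_names),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))


def build_reference_table(
    kinds: Sequence[str],
    spec: PriorSpec,
    n_sims: int,
    sample_sizes: Sequence[int],
    L: int = 866,
    seed: int | None = None,
    populations: tuple[str, str, str] = ("P1", "P2", "P3"),
) -> ReferenceTable:
    """Simulate ``n_sims`` (draw -> simulate -> summarize) rows per scenario.

    Fully seeded and deterministic; a failed simulation is skipped with a
    log entry (never silently retried with the same seed).  Tables built
    with disjoint seeds can be combined with :meth:`ReferenceTable.concat`.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    sizes = tuple(int(s) for s in sample_sizes)
    if len(sizes) != 3 or len(populations) != 3:
        raise ValueError(
            "the scenarios are 3-population models: exactly three groups "
            f"with n >= 2 each are required, got {len(sizes)}"
        )
    names = stat_names(populations)
    rng = np.random.default_rng(seed)
    rows = []
    for kind in kinds:
        for _ in range(n_sims):
            sim_seed = int(rng.integers(1, 2**31 - 1))
            scen, mu = sample_priors(spec, kind, rng, populations)
            try:
                G = simulate_matrix(scen, SimParams(mu, sizes, L, seed=sim_seed))
                stats = _stats_from_matrix(G, sizes, populations)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("simulation failed (seed %d): %s", sim_seed, exc)
                continue
            row = {
                "scenario": scen.scenario_id,
                "ne1": scen.ne[0], "ne2": scen.ne[1], "ne3": scen.ne[2],
                "ne_anc": scen.ne_ancestral,
                "t1": scen.t1,
                "t2": np.nan if scen.t2 is None else scen.t2,
                "mu": mu,
                "seed": sim_seed,
            }
            row.update(dict(zip(names, stats.values)))
            rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty or frame["scenario"].nunique() < len(set(kinds)):
        raise RuntimeError("reference-table simulation failed systematically; "
                           "see the log for per-row errors")
    return ReferenceTable(frame, names, spec, sizes, L)


# ---------------------------------------------------------------------------
# model choice


def _standardize(rt: ReferenceTable):
    X = rt.stats()
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    return 1.0 - (d / dmax) ** 2


def _softmax_rows(eta: np.ndarray) -> np.ndarray:
    z = np.column_stack([np.zeros(eta.shape[0]), np.clip(eta, -35, 35)])
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _weighted_mnlogit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      ridge: float = 1e-6, max_iter: int = 100):
    """Newton fit of a weighted multinomial logit (first class = reference).

    Returns (classes, B, H) with coefficient matrix B of shape
    (K-1, p) and the observed information H (including the ridge term).
    """
    classes = np.unique(y)
    K = classes.size
    m, p = X.shape
    Y = (y[:, None] == classes[None, :]).astype(float)
    B = np.zeros((K - 1, p))
    H = np.eye((K - 1) * p) * ridge
    for _ in range(max_iter):
        P = _softmax_rows(X @ B.T)
        grad = np.concatenate(
            [X.T @ (w * (P[:, k] - Y[:, k])) for k in range(1, K)]
        ) + ridge * B.ravel()
        H = np.zeros(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(1, K):
                wkl = w * P[:, k] * ((k == l) - P[:, l])
                H[(k - 1) * p:k * p, (l - 1) * p:l * p] = X.T @ (wkl[:, None] * X)
        H += ridge * np.eye((K - 1) * p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        B = B - step.reshape(K - 1, p)
        if np.abs(step).max() < 1e-10:
            break
    return classes, B, H


@dataclass(frozen=True)
class ModelChoiceResult:
    """Posterior scenario probabilities with 95% CIs."""

    table: pd.DataFrame  # columns scenario, prob, lo, hi
    selected: int
    n_closest: int

    @property
    def probabilities(self) -> dict[int, float]:
        return dict(zip(self.table["scenario"], self.table["prob"]))


def model_choice(
    obs: SummaryStatVector | np.ndarray,
    rt: ReferenceTable,
    n_closest: int | None = None,
) -> ModelChoiceResult:
    """Scenario posterior probabilities by weighted multinomial logistic
    regression over the ``n_closest`` reference rows nearest the observation.

    ``n_closest`` defaults to 1% of the table (the acceptance fraction used
    with 3,000 of 300,000 rows at full scale).  Statistics are standardized
    by the reference-table mean and standard deviation, which makes the
    result invariant to affine rescaling of any statistic.  The 95% CIs come
    from the asymptotic (delta-method) variance of the predicted
    probabilities at the observed point.
    """
    x_obs = obs.values if isinstance(obs, SummaryStatVector) else np.asarray(obs)
    if n_closest is None:
        # 1% acceptance fraction, floored so the local logistic regression
        # keeps more points than parameters at desk scale
        n_closest = min(rt.n_rows, max(int(round(0.01 * rt.n_rows)), 300))
    if n_closest > rt.n_rows:
        raise ValueError("n_closest exceeds the number of reference rows")
    Z, mean, scale = _standardize(rt)
    z_obs = (x_obs - mean) / scale
    d = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:n_closest]
    w = _epanechnikov(d[idx])
    y = rt.scenario_ids()[idx]
    all_ids = np.unique(rt.scenario_ids())
    present = np.unique(y)
    missing = [int(s) for s in all_ids if s not in present]
    if missing:
        warnings.warn(
            f"scenarios {missing} absent from the {n_closest} closest rows; "
            "their posterior probability is floored at 0"
        )
    Xd = np.column_stack([np.ones(idx.size), Z[idx]])
    x0 = np.concatenate([[1.0], z_obs])
    if present.size == 1:
        probs = {int(present[0]): (1.0, 1.0, 1.0)}
    else:
        classes, B, H = _weighted_mnlogit(Xd, y, w)
        eta = np.concatenate([[0.0], np.clip(B @ x0, -35, 35)])
        e = np.exp(eta - eta.max())
        pi = e / e.sum()
        Hinv = np.linalg.pinv(H)
        p = Xd.shape[1]
        K = classes.size
        probs = {}
        for c in range(K):
            g = np.concatenate(
                [pi[c] * ((c == k) - pi[k]) * x0 for k in range(1, K)]
            )
            se = float(np.sqrt(max(g @ Hinv @ g, 0.0)))
            lo = float(np.clip(pi[c] - 1.96 * se, 0.0, 1.0))
            hi = float(np.clip(pi[c] + 1.96 * se, 0.0, 1.0))
            probs[int(classes[c])] = (float(pi[c]), lo, hi)
    rows = []
    for s in all_ids:
        pr, lo, hi = probs.get(int(s), (0.0, 0.0, 0.0))
        rows.append({"scenario": int(s), "prob": pr, "lo": lo, "hi": hi})
    table = pd.DataFrame(rows)
    # renormalize point estimates so floored scenarios keep the sum at 1
    tot = table["prob"].sum()
    if tot > 0:
        table["prob"] = table["prob"] / tot
    selected = int(table.loc[table["prob"].idxmax(), "scenario"])
    return ModelChoiceResult(table, selected, n_closest)


# ---------------------------------------------------------------------------
# parameter estimation


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws)
    cum = cum / cum[-1]
    return float(np.interp(q, cum, xs))


def estimate_parameters(
    rt: ReferenceTable,
    scenario_id: int,
    obs: SummaryStatVector | np.ndarray,
    n_closest: int | None = None,
) -> pd.DataFrame:
    """Regression-adjusted parameter posteriors for one scenario.

    Accepted draws are the ``n_closest`` rows of the scenario nearest the
    observation; a weighted local-linear regression of the log parameters on
    the standardized statistics adjusts each draw to the observed point
    (Beaumont-style); the returned table holds the weighted median and
    2.5/97.5 percentiles, back-transformed to natural scale.
    """
    x_obs = obs.values if isinstance(obs, SummaryStatVector) else np.asarray(obs)
    sub = rt.frame[rt.frame["scenario"] == scenario_id]
    if sub.empty:
        raise ValueError(f"scenario {scenario_id} absent from the reference table")
    if n_closest is None:
        n_closest = min(len(sub), max(int(round(0.01 * rt.n_rows)), 300))
    if n_closest > len(sub):
        raise ValueError(
            f"n_closest={n_closest} exceeds the {len(sub)} rows of scenario "
            f"{scenario_id}"
        )
    Z_all, mean, scale = _standardize(rt)
    Z = Z_all[sub.index.to_numpy()]
    z_obs = (x_obs - mean) / scale
    d = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:n_closest]
    w = _epanechnikov(d[order])
    params = [p for p in PARAM_NAMES if sub[p].notna().all()]
    Y = np.log(sub.iloc[order][params].to_numpy(dtype=float))
    X = Z[order] - z_obs
    Xd = np.column_stack([np.ones(len(order)), X])
    sw = np.sqrt(w)
    try:
        beta, *_ = np.linalg.lstsq(Xd * sw[:, None], Y * sw[:, None], rcond=None)
        adjusted = Y - X @ beta[1:]
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        warnings.warn("singular local-linear regression; using unadjusted draws")
        adjusted = Y
    rows = []
    for j, name in enumerate(params):
        col = adjusted[:, j]
        rows.append({
            "param": name,
            "median": float(np.exp(_weighted_quantile(col, w, 0.5))),
            "q2.5": float(np.exp(_weighted_quantile(col, w, 0.025))),
            "q97.5": float(np.exp(_weighted_quantile(col, w, 0.975))),
        })
    return pd.DataFrame(rows)


def to_years(generations: float | np.ndarray, g: float = 10.0):
    """Convert generations to years via the generation time (default 10 y)."""
    if np.any(np.asarray(generations) < 0):
        raise ValueError("generations must be >= 0")
    return generations * g


# ---------------------------------------------------------------------------
# model/results facade


class ABCModel:
    """Scenario-choice ABC model for one observed dataset.

    Parameters
    ----------
    observed
        Observed :class:`SummaryStatVector` (see :func:`summary_statistics`
        or :meth:`from_alignment`).
    sample_sizes
        Per-group sample sizes used for the reference simulations (should
        match the observed groups).
    kinds
        Scenario kinds to compare (default: all three).
    priors, L, populations
        Prior bounds, sequence length and population names.
    """

    def __init__(
        self,
        observed: SummaryStatVector,
        sample_sizes: Sequence[int],
        kinds: Sequence[str] = SCENARIO_KINDS,
        priors: PriorSpec = PriorSpec(),
        L: int = 866,
        populations: tuple[str, str, str] | None = None,
    ) -> None:
        self.observed = observed
        self.sample_sizes = tuple(int(s) for s in sample_sizes)
        self.kinds = tuple(kinds)
        self.priors = priors
        self.L = int(L)
        self.populations = tuple(populations or observed.groups)
        self.reference: ReferenceTable | None = None

    @classmethod
    def from_alignment(
        cls,
        aln: Alignment,
        samples: SampleTable,
        partition: str = "group",
        groups: Sequence[str] | None = None,
        **kwargs,
    ) -> "ABCModel":
        obs = summary_statistics(aln, samples, partition, groups)
        sizes = [len([s for s in samples.ids_for(partition, g)
                      if s in aln.sample_ids]) for g in obs.groups]
        return cls(obs, sizes, L=aln.L, populations=obs.groups, **kwargs)

    def simulate_reference(self, n_sims: int, seed: int | None = None
                           ) -> ReferenceTable:
        """Build (and store) a reference table with n_sims rows per scenario."""
        self.reference = build_reference_table(
            self.kinds, self.priors, n_sims, self.sample_sizes, self.L,
            seed=seed, populations=self.populations,
        )
        return self.reference

    def fit(self, n_closest: int | None = None,
            generation_time: float = 10.0) -> "ABCResults":
        """Scenario choice plus parameter posteriors for the winner."""
        if self.reference is None:
            raise RuntimeError("call simulate_reference() before fit()")
        choice = model_choice(self.observed, self.reference, n_closest)
        n_scen = int((self.reference.scenario_ids() == choice.selected).sum())
        posteriors = estimate_parameters(
            self.reference, choice.selected, self.observed,
            min(choice.n_closest, n_scen),
        )
        return ABCResults(self, choice, posteriors, generation_time)


@dataclass
class ABCResults:
    """Scenario posteriors and parameter estimates from :class:`ABCModel`."""

    model: ABCModel
    choice: ModelChoiceResult
    posteriors: pd.DataFrame
    generation_time: float = 10.0

    @property
    def selected_scenario(self) -> int:
        return self.choice.selected

    @property
    def scenario_table(self) -> pd.DataFrame:
        return self.choice.table

    def times_in_years(self) -> pd.DataFrame:
        t = self.posteriors[self.posteriors["param"].isin(["t1", "t2"])].copy()
        for c in ("median", "q2.5", "q97.5"):
            t[c] = to_years(t[c], self.generation_time)
        return t

    def summary(self) -> str:
        lines = [
            "ABC scenario choice (logistic regression)",
            "-----------------------------------------",
            f"reference rows       {self.model.reference.n_rows}",
            f"closest rows used    {self.choice.n_closest}",
        ]
        for _, r in self.choice.table.iterrows():
            mark = " *" if int(r["scenario"]) == self.selected_scenario else ""
            lines.append(
                f"scenario {int(r['scenario'])}: {r['prob']:.3f} "
                f"[{r['lo']:.3f}-{r['hi']:.3f}]{mark}"
            )
        lines.append("")
        lines.append(f"posterior parameters, scenario {self.selected_scenario} "
                     f"(median [95% CI])")
        for _, r in self.posteriors.iterrows():
            lines.append(
                f"  {r['param']:<7} {r['median']:.4g} "
                f"[{r['q2.5']:.4g}-{r['q97.5']:.4g}]"
            )
        t = self.times_in_years()
        if not t.empty:
            lines.append(f"split times in years (generation time "
                         f"{self.generation_time:g} y):")
            for _, r in t.iterrows():
                lines.append(
                    f"  {r['param']:<7} {r['median']:,.0f} "
                    f"[{r['q2.5']:,.0f}-{r['q97.5']:,.0f}]"
                )
        return "\n".join(lines)
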