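"""Coalescent simulation of mtDNA alignments (msprime backend).

Conventions
-----------
mtDNA is a single non-recombining haploid locus: all effective sizes are
haploid ``Ne``, time is counted in generations, and samples have ploidy 1.
The scaled mutation parameter used by the mismatch model is
``theta = 2 * Ne * mu * L``.  The substitution model is Jukes-Cantor on a
finite sequence of ``L`` discrete sites (``ts/tv``-configurable K2P is not
implemented; base composition of real sequences is not imitated, invariant
sites are written as ``A``).

Three-population scenarios
--------------------------
``populations`` are ordered from the most recently founded group to the
putative origin (e.g. north -> south for a southern-refuge hypothesis).

``gradual_north_derived`` (scenario 1)
    Backward in time, pop 1 merges into pop 2 at ``t1`` and the remaining
    two merge into the ancestral population at ``t2`` (forward: stepwise
    diversification away from the origin at pop 3's side).
``gradual_south_derived`` (scenario 2)
    Mirror image: pop 3 merges into pop 2 at ``t1``; pops 1+2 merge into
    the ancestral population at ``t2``.
``sudden_trifurcation`` (scenario 3)
    All three populations split simultaneously from the ancestral
    population at ``t1`` (``t2`` unused).

No post-split migration is modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import msprime
import numpy as np

from .data_io import Alignment, SampleTable

GRADUAL_NORTH_DERIVED = "gradual_north_derived"
GRADUAL_SOUTH_DERIVED = "gradual_south_derived"
SUDDEN_TRIFURCATION = "sudden_trifurcation"
SCENARIO_KINDS = (GRADUAL_NORTH_DERIVED, GRADUAL_SOUTH_DERIVED, SUDDEN_TRIFURCATION)
#: scenario ids in the conventional 1/2/3 order
SCENARIO_IDS = {GRADUAL_NORTH_DERIVED: 1, GRADUAL_SOUTH_DERIVED: 2,
                SUDDEN_TRIFURCATION: 3}


@dataclass(frozen=True)
class Scenario:
    """A concrete 3-population demographic scenario (all parameters set)."""

    kind: str
    populations: tuple[str, str, str]
    ne: tuple[float, float, float]
    ne_ancestral: float
    t1: float
    t2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if any(x <= 0 for x in self.ne) or self.ne_ancestral <= 0:
            raise ValueError("all effective sizes must be > 0")
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if self.kind == SUDDEN_TRIFURCATION:
            if self.t2 is not None:
                raise ValueError("t2 is not part of the trifurcation scenario")
        else:
            if self.t2 is None or self.t1 > self.t2:
                raise ValueError(
                    f"gradual scenarios require t1 <= t2, got t1={self.t1}, t2={self.t2}"
                )

    @property
    def scenario_id(self) -> int:
        return SCENARIO_IDS[self.kind]


@dataclass(frozen=True)
class SimParams:
    """Mutation and sampling parameters for one simulation."""

    mu: float
    sample_sizes: tuple[int, ...]
    L: int = 866
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.L <= 0 or any(s < 1 for s in self.sample_sizes):
            raise ValueError("invalid simulation parameters")


def _safe_name(name: str) -> str:
    return re.sub(r"\W", "_", name)


def _demography(scenario: Scenario) -> tuple[msprime.Demography, list[str]]:
    names = [_safe_name(p) for p in scenario.populations]
    dem = msprime.Demography()
    for name, ne in zip(names, scenario.ne):
        dem.add_population(name=name, initial_size=ne)
    dem.add_population(name="ANC", initial_size=scenario.ne_ancestral)
    p1, p2, p3 = names
    if scenario.kind != SUDDEN_TRIFURCATION and scenario.t1 == scenario.t2:
        # zero-length intermediate epoch: exactly a trifurcation into ANC
        dem.add_population_split(time=scenario.t1, derived=[p1, p2, p3],
                                 ancestral="ANC")
    elif scenario.kind == GRADUAL_NORTH_DERIVED:
        dem.add_population_split(time=scenario.t1, derived=[p1], ancestral=p2)
        dem.add_population_split(time=scenario.t2, derived=[p2, p3], ancestral="ANC")
    elif scenario.kind == GRADUAL_SOUTH_DERIVED:
        dem.add_population_split(time=scenario.t1, derived=[p3], ancestral=p2)
        dem.add_population_split(time=scenario.t2, derived=[p1, p2], ancestral="ANC")
    else:
        dem.add_population_split(time=scenario.t1, derived=[p1, p2, p3],
                                 ancestral="ANC")
    dem.sort_events()
    return dem, names


def _two_seeds(seed: int | None) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    a, b = ss.generate_state(2, dtype=np.uint32)
    return int(a % (2**31 - 2) + 1), int(b % (2**31 - 2) + 1)


def _sim_tables(scenario: Scenario, p: SimParams):
    if len(p.sample_sizes) != 3:
        raise ValueError("three-population scenarios need three sample sizes")
    dem, names = _demography(scenario)
    s1, s2 = _two_seeds(p.seed)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n, population=name, ploidy=1)
                 for n, name in zip(p.sample_sizes, names)],
        demography=dem,
        sequence_length=p.L,
        ploidy=1,
        random_seed=s1,
    )
    return msprime.sim_mutations(ts, rate=p.mu, model=msprime.JC69(),
                                 random_seed=s2)


def _alignment_from_ts(ts, ids: Sequence[str], L: int) -> Alignment:
    mat = np.full((ts.num_samples, L), ord("A"), dtype=np.uint8)
    for v in ts.variants():
        pos = int(v.site.position)
        alleles = np.array([ord(a[0]) for a in v.alleles if a is not None],
                           dtype=np.uint8)
        mat[:, pos] = alleles[v.genotypes]
    return Alignment(tuple(ids), mat)


def simulate(scenario: Scenario, p: SimParams) -> tuple[Alignment, SampleTable]:
    """Simulate one mtDNA alignment under a 3-population scenario.

    Deterministic given (scenario, params, seed).  Sample ids are
    ``<group>_<k>``; the sample table assigns each individual to its
    population of origin (group column; lineage column is ``sim``).
    """
    mts = _sim_tables(scenario, p)
    ids, rows = [], []
    for name, n in zip(scenario.populations, p.sample_sizes):
        for k in range(n):
            sid = f"{_safe_name(name)}_{k:03d}"
            ids.append(sid)
            rows.append((sid, "sim", name, ""))
    aln = _alignment_from_ts(mts, ids, p.L)
    return aln, SampleTable.from_records(rows)


def simulate_matrix(scenario: Scenario, p: SimParams) -> np.ndarray:
    """Fast path for ABC: allele-index matrix of shape (n_samples, n_sites).

    Invariant sites are omitted (they contribute nothing to any summary
    statistic used here); samples are ordered population by population.
    """
    mts = _sim_tables(scenario, p)
    g = mts.genotype_matrix()  # (sites, samples)
    return g.T.astype(np.int16)


def sudden_expansion_demography(
    theta0: float,
    theta1: float,
    tau: float,
    n: int,
    L: int,
    seed: int | None = None,
    mu: float = 5e-7,
) -> tuple[Alignment, SampleTable]:
    """Single population whose scaled size jumps from theta1 (present) back
    to theta0 at tau mutational units before present.

    The mismatch-model parameters are mapped onto the coalescent via
    ``theta = 2*Ne*mu*L`` and ``tau = 2*mu*L*t`` (t in generations); ``mu``
    only fixes this change of units and does not affect the distribution of
    the resulting statistics.
    """
    if min(theta0, theta1, tau) < 0:
        raise ValueError("theta0, theta1 and tau must be >= 0")
    uL = mu * L
    n1 = max(theta1 / (2 * uL), 1e-6)
    n0 = max(theta0 / (2 * uL), 1e-6)
    t_change = tau / (2 * uL)
    dem = msprime.Demography()
    # tau == 0 means the change already happened: equilibrium at theta0
    dem.add_population(name="pop", initial_size=n1 if t_change > 0 else n0)
    if t_change > 0:
        dem.add_population_parameters_change(time=t_change, initial_size=n0,
                                             population="pop")
    s1, s2 = _two_seeds(seed)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n, population="pop", ploidy=1)],
        demography=dem, sequence_length=L, ploidy=1, random_seed=s1,
    )
    mts = msprime.sim_mutations(ts, rate=mu, model=msprime.JC69(),
                                random_seed=s2)
    ids = [f"pop_{k:03d}" for k in range(n)]
    aln = _alignment_from_ts(mts, ids, L)
    return aln, SampleTable.from_records([(i, "sim", "pop", "") for i in ids])


def constant_population(
    theta: float, n: int, L: int, seed: int | None = None, mu: float = 5e-7
) -> tuple[Alignment, SampleTable]:
    """Neutral constant-size haploid population at scaled size theta."""
    return sudden_expansion_demography(theta, theta, 0.0, n, L, seed=seed, mu=mu)
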