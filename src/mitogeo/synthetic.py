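"""Seeded synthetic fixtures emulating the study's lineage structures.

Three deterministic sequence-level generators emulate the qualitative
structures seen in the empirical lineages, plus a pseudo-observed dataset
generator for ABC recovery experiments:

``make_star_expansion``
    One high-frequency central haplotype surrounded by rare tips one step
    away (demographic-expansion signature: star network, unimodal mismatch,
    negative Tajima's D / Fu's F_S).
``make_two_refuge``
    Two haplotype clusters assigned to disjunct North/South groups, with a
    configurable number of mutation steps between the exclusive cluster
    cores and a configurable number of shared haplotypes (default one).
``make_bimodal_pair``
    Two co-distributed star subclusters whose centres differ by a small
    number of steps (default two), members interleaved across groups.
``make_pseudoobs``
    One coalescent draw under a 3-population scenario with the ground
    truth persisted as a JSON sidecar.

Every generator plants variant sites at disjoint alignment columns, so all
inter-haplotype step counts are exact by construction, and is fully
deterministic given its parameters and seed.  Base composition of real
mtDNA is not imitated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .coalsim import Scenario, SimParams, simulate
from .data_io import Alignment, SampleTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str  # star_expansion | two_refuge | bimodal_pair | scenario_pseudoobs
    params: dict
    seed: int


def make_fixture(spec: FixtureSpec):
    fn = {
        "star_expansion": make_star_expansion,
        "two_refuge": make_two_refuge,
        "bimodal_pair": make_bimodal_pair,
        "scenario_pseudoobs": make_pseudoobs,
    }.get(spec.kind)
    if fn is None:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return fn(**spec.params, seed=spec.seed)


def _base_sequence(rng: np.random.Generator, L: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=L)]


def _mutate(seq: np.ndarray, sites: Sequence[int],
            rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        choices = _BASES[_BASES != out[s]]
        out[s] = choices[rng.integers(0, 3)]
    return out


class _SitePool:
    """Hands out previously unused alignment columns (disjoint variants)."""

    def __init__(self, L: int, rng: np.random.Generator):
        self._free = list(rng.permutation(L))

    def take(self, k: int) -> list[int]:
        if k > len(self._free):
            raise ValueError("alignment too short for the requested variant sites")
        out = self._free[:k]
        del self._free[:k]
        return [int(s) for s in out]


def _build(seqs: list[np.ndarray], counts: list[int], groups: list[str],
           lineage: str, prefix: str) -> tuple[Alignment, SampleTable]:
    ids, rows, mat = [], [], []
    k = 0
    for seq, c, grp in zip(seqs, counts, groups):
        for _ in range(c):
            k += 1
            sid = f"{prefix}{k:03d}"
            ids.append(sid)
            rows.append((sid, lineage, grp, ""))
            mat.append(seq)
    aln = Alignment(tuple(ids), np.vstack(mat))
    return aln, SampleTable.from_records(rows)


def make_star_expansion(
    n: int = 50,
    L: int = 866,
    n_tip_haplotypes: int = 12,
    seed: int | None = None,
    group: str = "North",
    lineage: str = "blue",
) -> tuple[Alignment, SampleTable]:
    """Star cluster: one central haplotype plus rare tips one step away.

    The central haplotype has frequency ``n - n_tip_haplotypes``; each of
    the ``n_tip_haplotypes`` tips occurs once and differs from the centre at
    its own private site.
    """
    if n_tip_haplotypes >= n:
        raise ValueError("n_tip_haplotypes must be < n")
    rng = np.random.default_rng(seed)
    pool = _SitePool(L, rng)
    centre = _base_sequence(rng, L)
    seqs = [centre]
    counts = [n - n_tip_haplotypes]
    for _ in range(n_tip_haplotypes):
        seqs.append(_mutate(centre, pool.take(1), rng))
        counts.append(1)
    return _build(seqs, counts, [group] * len(seqs), lineage, "s")


def make_two_refuge(
    nN: int = 40,
    nS: int = 25,
    inter_cluster_steps: int = 4,
    n_shared: int = 1,
    seed: int | None = None,
    L: int = 866,
    n_tips_north: int = 6,
    n_tips_south: int = 5,
    lineage: str = "yellow",
) -> tuple[Alignment, SampleTable]:
    """Two-refuge disjunct structure (North/South) with shared haplotypes.

    The exclusive cluster cores (the northern and southern central
    haplotypes) lie exactly ``inter_cluster_steps`` apart; ``n_shared``
    haplotypes (tips of the northern core) occur in both groups.  The
    northern group is dominated by its core (low haplotype diversity), the
    southern haplotypes are near-equifrequent (high haplotype diversity),
    emulating 'southern richness and northern purity' in reverse sampling.
    """
    if inter_cluster_steps < 2:
        raise ValueError("inter_cluster_steps must be >= 2")
    if n_shared < 0 or n_shared > min(nN, nS) - 1:
        raise ValueError("inconsistent n_shared")
    rng = np.random.default_rng(seed)
    pool = _SitePool(L, rng)
    core_n = _base_sequence(rng, L)
    core_s = _mutate(core_n, pool.take(inter_cluster_steps), rng)

    seqs: list[np.ndarray] = []
    counts: list[int] = []
    groups: list[str] = []

    # shared haplotypes: one copy in each group
    for _ in range(n_shared):
        hap = _mutate(core_n, pool.take(1), rng)
        seqs += [hap, hap]
        counts += [1, 1]
        groups += ["North", "South"]

    # northern cluster: dominant core + rare tips
    n_core_n = nN - n_tips_north - n_shared
    if n_core_n < 1:
        raise ValueError("nN too small for the requested tips and shared haplotypes")
    seqs.append(core_n)
    counts.append(n_core_n)
    groups.append("North")
    for _ in range(n_tips_north):
        seqs.append(_mutate(core_n, pool.take(1), rng))
        counts.append(1)
        groups.append("North")

    # southern cluster: near-equifrequent core + tips
    n_south = nS - n_shared
    k = n_tips_south + 1
    if n_south < k:
        raise ValueError("nS too small for the requested southern tips")
    base_count, rem = divmod(n_south, k)
    seqs.append(core_s)
    counts.append(base_count + (1 if rem > 0 else 0))
    groups.append("South")
    for t in range(n_tips_south):
        steps = 1 if t % 2 == 0 else 2
        seqs.append(_mutate(core_s, pool.take(steps), rng))
        counts.append(base_count + (1 if t + 1 < rem else 0))
        groups.append("South")
    return _build(seqs, counts, groups, lineage, "y")


def make_bimodal_pair(
    n: int = 40,
    L: int = 866,
    centre_distance: int = 2,
    seed: int | None = None,
    n_tips_per_cluster: int = 4,
    lineage: str = "red",
) -> tuple[Alignment, SampleTable]:
    """Two co-distributed star subclusters with centres a few steps apart.

    Each subcluster is a frequent central haplotype with
    ``n_tips_per_cluster`` singleton tips one step away; the two centres
    differ by exactly ``centre_distance`` steps.  Members of both
    subclusters are interleaved across the North/South groups (no
    geographic signal), mirroring a structured refugium whose sublineages
    spread together.
    """
    if centre_distance < 1:
        raise ValueError("centre_distance must be >= 1")
    n_tips = 2 * n_tips_per_cluster
    if n - n_tips < 2:
        raise ValueError("n too small for the requested tips")
    rng = np.random.default_rng(seed)
    pool = _SitePool(L, rng)
    c1 = _base_sequence(rng, L)
    c2 = _mutate(c1, pool.take(centre_distance), rng)
    n_c1 = (n - n_tips + 1) // 2
    n_c2 = n - n_tips - n_c1
    seqs = [c1, c2]
    counts = [n_c1, n_c2]
    for centre in (c1, c2):
        for _ in range(n_tips_per_cluster):
            seqs.append(_mutate(centre, pool.take(1), rng))
            counts.append(1)
    groups = ["North" if i % 2 == 0 else "South" for i in range(len(seqs))]
    return _build(seqs, counts, groups, lineage, "r")


def make_pseudoobs(
    scenario: Scenario,
    sample_sizes: Sequence[int],
    mu: float,
    L: int = 866,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> tuple[Alignment, SampleTable, dict]:
    """One pseudo-observed coalescent dataset with its ground truth.

    Returns (alignment, sample table, truth record); when ``outdir`` is
    given the three are also written as FASTA, TSV and a JSON sidecar.
    """
    aln, table = simulate(scenario, SimParams(mu, tuple(sample_sizes), L, seed))
    truth = {
        "kind": scenario.kind,
        "scenario_id": scenario.scenario_id,
        "populations": list(scenario.populations),
        "ne": list(scenario.ne),
        "ne_ancestral": scenario.ne_ancestral,
        "t1": scenario.t1,
        "t2": scenario.t2,
        "mu": mu,
        "L": L,
        "sample_sizes": list(sample_sizes),
        "seed": seed,
    }
    if outdir is not None:
        from .data_io import write_alignment, write_sample_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(aln, outdir / "pseudoobs.fasta")
        write_sample_table(table, outdir / "pseudoobs.tsv")
        (outdir / "pseudoobs.truth.json").write_text(json.dumps(truth, indent=1))
    return aln, table, truth
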