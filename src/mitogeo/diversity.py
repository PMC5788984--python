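"""Genetic diversity indices and rarefaction.

Implements the per-group indices used in refugium inference: number of
segregating sites ``S``, nucleotide diversity ``pi`` (mean per-site
proportion of pairwise differences), number of haplotypes ``h``, number of
private haplotypes ``h_P`` and haplotype diversity ``Hd`` (Nei's unbiased
estimator, ``n/(n-1) * (1 - sum (f_i/n)^2)``).

All indices are computed on the usable sites of the complete-deletion mask
of the *full* alignment by default, so rarefied and total indices remain
commensurable; a per-subset re-mask is available.

Rarefaction follows the scheme of drawing, for each group larger than the
smallest one of size ``N``, a subsample of ``N`` individuals without
replacement, computing all indices, repeating (default five times) and
averaging.  Draws are seeded through a spawning master seed so every
group/repetition stream is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    Alignment,
    COMPLETE_DELETION,
    HaplotypeTable,
    SampleTable,
    collapse_haplotypes,
    usable_sites,
)


@dataclass(frozen=True)
class DiversityIndices:
    """One report row of per-group diversity indices."""

    group: str
    n: int
    S: int | float
    h: int | float
    h_P: int | float | None
    Hd: float
    pi: float  # per-site; reported x 10^3 at display time

    def as_report_row(self) -> dict:
        d = asdict(self)
        d["Hd"] = round(float(self.Hd), 3)
        d["pi_e3"] = round(float(self.pi) * 1e3, 2)
        del d["pi"]
        return d


def _usable_submatrix(aln: Alignment, ids: Sequence[str], global_mask: bool) -> np.ndarray:
    sub = aln.subset(list(ids))
    mask = usable_sites(aln if global_mask else sub, COMPLETE_DELETION)
    return sub.matrix[:, mask]


def segregating_sites(aln: Alignment, ids: Sequence[str] | None = None,
                      global_mask: bool = True) -> int:
    """Number of usable columns with >= 2 distinct bases among the sequences."""
    ids = list(ids) if ids is not None else list(aln.sample_ids)
    if len(ids) < 2:
        raise ValueError("segregating sites require n >= 2")
    m = _usable_submatrix(aln, ids, global_mask)
    return int((m != m[0]).any(axis=0).sum())


def mean_pairwise_differences(aln: Alignment, ids: Sequence[str] | None = None,
                              global_mask: bool = True) -> float:
    """Mean number of differing sites over all unordered sequence pairs."""
    ids = list(ids) if ids is not None else list(aln.sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("pairwise differences require n >= 2")
    m = _usable_submatrix(aln, ids, global_mask)
    # per-site allele counting: sum over pairs of differences equals
    # sum over sites of (#pairs with distinct alleles)
    total = 0.0
    for a in np.unique(m):
        c = (m == a).sum(axis=0)
        total += float((c * (n - c)).sum())
    return total / 2.0 / (n * (n - 1) / 2)


def nucleotide_diversity(aln: Alignment, ids: Sequence[str] | None = None,
                         global_mask: bool = True) -> float:
    """Nucleotide diversity: mean pairwise differences per usable site."""
    ids = list(ids) if ids is not None else list(aln.sample_ids)
    m = _usable_submatrix(aln, ids, global_mask)
    if m.shape[1] == 0:
        raise ValueError("no usable sites")
    return mean_pairwise_differences(aln, ids, global_mask) / m.shape[1]


def haplotype_diversity(freqs: Sequence[int], n: int | None = None) -> float:
    """Nei's haplotype diversity with the small-sample correction."""
    f = np.asarray(freqs, dtype=float)
    ntot = int(f.sum()) if n is None else int(n)
    if n is not None and int(f.sum()) != ntot:
        raise ValueError("frequencies do not sum to n")
    if ntot < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    return ntot / (ntot - 1) * (1.0 - float(((f / ntot) ** 2).sum()))


def private_haplotypes(ht: HaplotypeTable, group: str) -> int:
    """Haplotypes present in ``group`` and absent from every other group."""
    groups = ht.group_names()
    if group not in groups:
        raise ValueError(f"unknown group {group!r}; known: {groups}")
    count = 0
    for hap in ht.haplotypes:
        own = hap.group_frequencies.get(group, 0)
        others = sum(v for g, v in hap.group_frequencies.items() if g != group)
        if own > 0 and others == 0:
            count += 1
    return count


def _group_indices(
    aln: Alignment,
    ids: Sequence[str],
    group: str,
    ht: HaplotypeTable | None,
    global_mask: bool,
) -> DiversityIndices:
    ids = list(ids)
    n = len(ids)
    sub_ht = _collapse_ids(aln, ids, global_mask)
    h = sub_ht.h
    hp = private_haplotypes(ht, group) if ht is not None else None
    if n < 2:
        return DiversityIndices(group, n, float("nan"), h, hp, float("nan"), float("nan"))
    return DiversityIndices(
        group,
        n,
        segregating_sites(aln, ids, global_mask),
        h,
        hp,
        haplotype_diversity(sub_ht.frequencies),
        nucleotide_diversity(aln, ids, global_mask),
    )


def _collapse_ids(aln: Alignment, ids: Sequence[str], global_mask: bool) -> HaplotypeTable:
    sub = aln.subset(list(ids))
    if global_mask:
        mask = usable_sites(aln, COMPLETE_DELETION)
        keyed = sub.matrix[:, mask]
        # collapse on the global mask by hand (cheap)
        seen: dict[bytes, int] = {}
        for i in range(sub.n):
            k = keyed[i].tobytes()
            seen[k] = seen.get(k, 0) + 1
        from .data_io import Haplotype

        haps = tuple(
            Haplotype(f"H{i+1}", "", c, {"all": c})
            for i, (k, c) in enumerate(
                sorted(seen.items(), key=lambda kv: -kv[1])
            )
        )
        return HaplotypeTable(haps, tuple(int(c) + 1 for c in mask))
    return collapse_haplotypes(sub)


def diversity_profile(
    aln: Alignment,
    samples: SampleTable,
    partition: str = "group",
    global_mask: bool = True,
) -> list[DiversityIndices]:
    """One row of indices per group of the partition column.

    Private haplotypes are counted against the other groups of the same
    partition.  Groups with ``n < 2`` are flagged by NaN for the indices
    that require two sequences.
    """
    ht = collapse_haplotypes(aln, samples, group_by=partition)
    rows = []
    for group in samples.groups(partition):
        ids = [s for s in samples.ids_for(partition, group) if s in aln.sample_ids]
        if not ids:
            continue
        rows.append(_group_indices(aln, ids, group, ht, global_mask))
    return rows


def profile_frame(rows: Sequence[DiversityIndices]) -> pd.DataFrame:
    """Report table with display rounding (Hd 3 d.p., pi x 10^3 to 2 d.p.)."""
    return pd.DataFrame([r.as_report_row() for r in rows])[
        ["group", "n", "S", "h", "h_P", "Hd", "pi_e3"]
    ]


def rarefy(
    aln: Alignment,
    samples: SampleTable,
    group: str,
    target_n: int | None = None,
    reps: int = 5,
    seed: int | None = None,
    partition: str = "group",
    global_mask: bool = True,
) -> DiversityIndices:
    """Mean diversity indices over seeded random subsamples of one group.

    ``target_n`` defaults to the size of the smallest group of the
    partition.  Each repetition draws ``target_n`` individuals without
    replacement; indices are averaged arithmetically over repetitions.
    Private haplotypes are not rarefied (they depend on the other groups)
    and are reported as None.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ids = [s for s in samples.ids_for(partition, group) if s in aln.sample_ids]
    if not ids:
        raise ValueError(f"group {group!r} has no samples in the alignment")
    if target_n is None:
        sizes = [
            len([s for s in samples.ids_for(partition, g) if s in aln.sample_ids])
            for g in samples.groups(partition)
        ]
        target_n = min(s for s in sizes if s > 0)
    if target_n > len(ids):
        raise ValueError(f"target_n {target_n} exceeds group size {len(ids)}")
    streams = np.random.SeedSequence(seed).spawn(reps)
    acc = {"S": [], "h": [], "Hd": [], "pi": []}
    for ss in streams:
        rng = np.random.default_rng(ss)
        draw = [ids[i] for i in rng.choice(len(ids), size=target_n, replace=False)]
        sub_ht = _collapse_ids(aln, draw, global_mask)
        acc["h"].append(sub_ht.h)
        if target_n >= 2:
            acc["S"].append(segregating_sites(aln, draw, global_mask))
            acc["Hd"].append(haplotype_diversity(sub_ht.frequencies))
            acc["pi"].append(nucleotide_diversity(aln, draw, global_mask))
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return DiversityIndices(
        f"{group} (rarefied n={target_n})",
        target_n,
        mean(acc["S"]),
        mean(acc["h"]),
        None,
        mean(acc["Hd"]),
        mean(acc["pi"]),
    )
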