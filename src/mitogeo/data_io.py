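"""Alignment and sample-table I/O, haplotype collapsing, pairwise differences.

The unit of analysis is a pre-aligned set of equal-length mtDNA sequences
(one record per individual) together with a sample table assigning each
individual to a mitochondrial lineage and to geographic groups/subgroups.

Missing-data policy
-------------------
Only the four canonical bases ``A C G T`` are treated as observed.  Gaps
(``-``), ``N`` and IUPAC ambiguity codes are treated as missing, because
mutation-step counting must be unambiguous.  Two policies are supported:

``complete_deletion`` (default)
    Alignment columns containing anything but ``A C G T`` in *any* record
    are excluded everywhere.  This is the convention used for all diversity
    indices so that every statistic is computed on the same set of sites.
``pairwise_deletion``
    All columns are retained; for each pair of sequences only columns where
    *both* members carry an observed base are compared.

Coordinates are 0-based internally; reported site positions are 1-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

COMPLETE_DELETION = "complete_deletion"
PAIRWISE_DELETION = "pairwise_deletion"
_POLICIES = (COMPLETE_DELETION, PAIRWISE_DELETION)

#: byte codes of the observed (unambiguous) nucleotide states
_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_policy(policy: str) -> None:
    if policy not in _POLICIES:
        raise ValueError(f"unknown missing-data policy {policy!r}; choose from {_POLICIES}")


@dataclass(frozen=True)
class Alignment:
    """Equal-length nucleotide sequences, one record per individual.

    Sequences are stored upper-cased with U mapped to T, as a byte matrix of
    shape ``(n, L)`` (ASCII codes).
    """

    sample_ids: tuple[str, ...]
    matrix: np.ndarray  # uint8, shape (n, L)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape inconsistent with sample ids")
        if self.n < 1 or self.L < 1:
            raise ValueError("alignment must contain >=1 record of length >=1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in alignment")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode("ascii")

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in alignment") from None

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        idx = [self.index_of(s) for s in sample_ids]
        return Alignment(tuple(sample_ids), self.matrix[idx])

    @classmethod
    def from_sequences(cls, ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        seqs = [_normalize(s) for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            bad = [(i, len(s)) for i, s in zip(ids, seqs)]
            raise ValueError(f"ragged alignment, (id, length) pairs: {bad}")
        mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        return cls(tuple(str(i) for i in ids), mat.reshape(len(seqs), -1).copy())


def _normalize(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; enforce equal lengths and unique ids."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [_normalize(str(r.seq)) for r in records]
    L0 = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != L0:
            raise ValueError(
                f"record {rid!r} has length {len(s)}, expected {L0}: alignment is ragged"
            )
    return Alignment.from_sequences(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write FASTA wrapped at 70 columns."""
    recs = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.sample_ids[i], description="")
        for i in range(aln.n)
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# sample table


@dataclass(frozen=True)
class SampleTable:
    """Per-individual metadata: lineage, group, subgroup (may be empty)."""

    frame: pd.DataFrame  # columns sample_id, lineage, group, subgroup

    def __post_init__(self) -> None:
        req = ["sample_id", "lineage", "group", "subgroup"]
        missing = [c for c in req if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in sample table: {dup}")
        if (self.frame["lineage"].astype(str).str.len() == 0).any():
            raise ValueError("empty lineage in sample table")

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str, str]]) -> "SampleTable":
        df = pd.DataFrame(rows, columns=["sample_id", "lineage", "group", "subgroup"])
        return cls(df.astype(str))

    def ids_for(self, column: str, value: str) -> list[str]:
        if column not in self.frame.columns:
            raise KeyError(f"unknown partition column {column!r}")
        return self.frame.loc[self.frame[column] == value, "sample_id"].tolist()

    def groups(self, column: str = "group") -> list[str]:
        vals = [v for v in self.frame[column].unique().tolist() if v not in ("", ".")]
        return vals


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df["subgroup"] = df.get("subgroup", "").replace(".", "")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    df = table.frame.copy()
    df["subgroup"] = df["subgroup"].replace("", ".")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# usable sites


def usable_sites(aln: Alignment, policy: str = COMPLETE_DELETION) -> np.ndarray:
    """Return the 0-based columns usable under the missing-data policy.

    Under ``complete_deletion`` these are the columns with an observed base
    in every record; zero such columns is a hard error.  Under
    ``pairwise_deletion`` all columns are returned (the per-pair mask is
    applied by the pairwise-difference functions).
    """
    _check_policy(policy)
    if policy == PAIRWISE_DELETION:
        return np.arange(aln.L)
    ok = np.isin(aln.matrix, _VALID).all(axis=0)
    cols = np.flatnonzero(ok)
    if cols.size == 0:
        raise ValueError("no usable sites under complete deletion")
    return cols


# ---------------------------------------------------------------------------
# haplotypes


@dataclass(frozen=True)
class Haplotype:
    label: str
    sequence: str  # full-length representative sequence
    frequency: int
    group_frequencies: Mapping[str, int]


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]
    site_mask: tuple[int, ...]  # 1-based alignment columns used for identity
    members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def labels(self) -> list[str]:
        return [hap.label for hap in self.haplotypes]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([hap.frequency for hap in self.haplotypes], dtype=int)

    @property
    def n(self) -> int:
        return int(self.frequencies.sum())

    def group_names(self) -> list[str]:
        names: list[str] = []
        for hap in self.haplotypes:
            for g in hap.group_frequencies:
                if g not in names:
                    names.append(g)
        return names


def collapse_haplotypes(
    aln: Alignment,
    samples: SampleTable | None = None,
    policy: str = COMPLETE_DELETION,
    group_by: str = "group",
    label_map: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with per-group counts.

    Identity is decided on the usable sites of the policy: records made
    identical by excluded columns merge.  Haplotypes are ordered by
    descending total frequency, ties by first occurrence, and labelled
    ``H1, H2, ...`` unless ``label_map`` (keyed by default label) overrides.
    Samples listed in the table but absent from the alignment are skipped
    with a warning.
    """
    _check_policy(policy)
    if samples is not None:
        known = [s for s in samples.frame["sample_id"] if s in aln.sample_ids]
        missing = [s for s in samples.frame["sample_id"] if s not in aln.sample_ids]
        if missing:
            warnings.warn(f"samples absent from alignment, skipped: {missing}")
            logger.warning("samples absent from alignment, skipped: %s", missing)
        sub = aln.subset(known)
        groups = dict(zip(samples.frame["sample_id"], samples.frame[group_by]))
    else:
        sub = aln
        groups = {s: "all" for s in aln.sample_ids}

    if policy == COMPLETE_DELETION:
        mask = usable_sites(sub, policy)
    else:
        mask = np.arange(sub.L)
    keyed = sub.matrix[:, mask]

    order: list[bytes] = []
    by_key: dict[bytes, list[int]] = {}
    for i in range(sub.n):
        k = keyed[i].tobytes()
        if k not in by_key:
            by_key[k] = []
            order.append(k)
        by_key[k].append(i)

    ranked = sorted(order, key=lambda k: (-len(by_key[k]), order.index(k)))
    group_names = sorted({groups[s] for s in sub.sample_ids})
    haps: list[Haplotype] = []
    members: dict[str, tuple[str, ...]] = {}
    for rank, k in enumerate(ranked, start=1):
        idx = by_key[k]
        default = f"H{rank}"
        label = label_map.get(default, default) if label_map else default
        ids = tuple(sub.sample_ids[i] for i in idx)
        gf = {g: 0 for g in group_names}
        for s in ids:
            gf[groups[s]] += 1
        haps.append(Haplotype(label, sub.sequence(idx[0]), len(idx), gf))
        members[label] = ids
    return HaplotypeTable(tuple(haps), tuple(int(c) + 1 for c in mask), members)


def write_haplotype_table(ht: HaplotypeTable, path: str | Path) -> None:
    groups = ht.group_names()
    rows = []
    for hap in ht.haplotypes:
        row = {"label": hap.label, "sequence": hap.sequence, "total_freq": hap.frequency}
        for g in groups:
            row[g] = hap.group_frequencies.get(g, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pairwise differences


@dataclass(frozen=True)
class DiffMatrix:
    """Symmetric matrix of mutation-step counts with label index."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # int, square

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix/label shape mismatch")
        if (m != m.T).any() or np.diag(m).any():
            raise ValueError("difference matrix must be symmetric with zero diagonal")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: Sequence[str]) -> "DiffMatrix":
        idx = [self.index_of(l) for l in labels]
        return DiffMatrix(tuple(labels), self.matrix[np.ix_(idx, idx)])


def _diff_counts(mat: np.ndarray, policy: str) -> np.ndarray:
    valid = np.isin(mat, _VALID)
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=int)
    if policy == COMPLETE_DELETION:
        cols = valid.all(axis=0)
        m = mat[:, cols]
        for i in range(n):
            out[i] = (m != m[i]).sum(axis=1)
    else:
        for i in range(n):
            both = valid & valid[i]
            out[i] = ((mat != mat[i]) & both).sum(axis=1)
    np.fill_diagonal(out, 0)
    return out


def pairwise_diff_matrix(
    obj: Alignment | HaplotypeTable, policy: str = COMPLETE_DELETION
) -> DiffMatrix:
    """Count differing sites between every pair of sequences/haplotypes."""
    _check_policy(policy)
    if isinstance(obj, HaplotypeTable):
        labels = tuple(obj.labels)
        seqs = [hap.sequence for hap in obj.haplotypes]
        mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
            len(seqs), -1
        )
    else:
        labels = tuple(obj.sample_ids)
        mat = obj.matrix
    return DiffMatrix(labels, _diff_counts(mat, policy))
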