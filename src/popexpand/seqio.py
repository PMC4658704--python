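"""Alignment and metadata I/O, haplotype collapsing, pairwise genetic distances.

The universal input of the pipeline is a pre-aligned set of equal-length
mitochondrial sequences (FASTA) plus an optional per-individual metadata
table (``id,locality,lat,lon``).  Distances are offered as raw site
differences, p-distance, or the Tamura–Nei (TN93) closed form, all under
pairwise deletion of gaps/ambiguities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_CHARS = set("ACGTN-")
RESOLVED = "ACGT"

__all__ = [
    "Alignment",
    "SampleMetadata",
    "HaplotypeTable",
    "DistanceMatrix",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "collapse_haplotypes",
    "pairwise_distance",
]


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged lengths, duplicate ids, empty input)."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences over {A,C,G,T,N,-} with unique ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment is empty")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        self.seqs = [s.upper() for s in self.seqs]
        bad = set("".join(self.seqs)) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")
        if self.length == 0:
            raise AlignmentError("alignment has zero columns")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """(n, L) matrix of ASCII codes (uint8) of the alignment."""
        return np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            self.n, self.length
        )


@dataclass
class SampleMetadata:
    """Georeferenced sample table: one row per individual."""

    table: pd.DataFrame  # columns: id, locality, lat, lon

    def __post_init__(self) -> None:
        required = {"id", "locality", "lat", "lon"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate ids in metadata")
        if (self.table["lat"].abs() > 90).any() or (self.table["lon"].abs() > 180).any():
            raise ValueError("coordinates out of range")

    def locality_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample id not in metadata: {sample_id}")
        return str(row["locality"].iloc[0])

    def localities(self) -> pd.DataFrame:
        """One row per locality with its (lat, lon); coordinates must be consistent."""
        grp = self.table.groupby("locality", sort=False)[["lat", "lon"]].first().reset_index()
        return grp


@dataclass
class HaplotypeTable:
    """Distinct sequences with multiplicities, member ids and per-locality counts."""

    sequences: list[str]
    counts: list[int]
    members: list[list[str]]
    locality_counts: pd.DataFrame | None = None  # index haplotype_id, columns localities
    ids: list[str] = field(default_factory=list)  # haplotype ids, H1..Hk

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"H{i + 1}" for i in range(len(self.sequences))]

    @property
    def k(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n

    def representative_alignment(self) -> Alignment:
        return Alignment(ids=list(self.ids), seqs=list(self.sequences))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": self.ids,
                "count": self.counts,
                "members": [";".join(m) for m in self.members],
                "sequence": self.sequences,
            }
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix tagged with its model and units."""

    ids: list[str]
    values: np.ndarray
    model: str  # raw_differences | p_distance | TN93
    units: str  # "sites" | "substitutions/site"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def read_alignment(path) -> Alignment:
    """Read a FASTA file into an :class:`Alignment` (wrapped or single-line)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids=[r.id for r in records], seqs=[str(r.seq) for r in records])


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def read_metadata(path) -> SampleMetadata:
    """Read the ``id,locality,lat,lon`` CSV."""
    return SampleMetadata(pd.read_csv(path, dtype={"id": str, "locality": str}))


def collapse_haplotypes(
    aln: Alignment,
    meta: SampleMetadata | None = None,
    resolved_only: bool = False,
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes (first-seen order).

    By default two sequences belong to one haplotype iff they are
    string-identical.  With ``resolved_only=True`` sites where either
    sequence carries N/- are ignored in the comparison, *and* the
    sequences must still be string-identical at every resolved site
    (useful when ambiguities are sequencing artefacts).
    """
    if meta is not None:
        known = set(meta.table["id"])
        missing = [i for i in aln.ids if i not in known]
        if missing:
            raise ValueError(f"metadata missing ids: {missing[:5]}")

    groups: list[int] = []  # haplotype index per sequence
    reps: list[str] = []
    for seq in aln.seqs:
        assigned = None
        for hi, rep in enumerate(reps):
            if resolved_only:
                same = all(a == b for a, b in zip(seq, rep) if a in RESOLVED and b in RESOLVED)
            else:
                same = seq == rep
            if same:
                assigned = hi
                break
        if assigned is None:
            reps.append(seq)
            assigned = len(reps) - 1
        groups.append(assigned)

    members: list[list[str]] = [[] for _ in reps]
    for sid, hi in zip(aln.ids, groups):
        members[hi].append(sid)
    counts = [len(m) for m in members]

    loc_counts = None
    if meta is not None:
        locs = list(dict.fromkeys(meta.table["locality"]))
        data = np.zeros((len(reps), len(locs)), dtype=int)
        loc_by_id = dict(zip(meta.table["id"], meta.table["locality"]))
        for hi, mem in enumerate(members):
            for sid in mem:
                data[hi, locs.index(loc_by_id[sid])] += 1
        loc_counts = pd.DataFrame(data, index=[f"H{i + 1}" for i in range(len(reps))], columns=locs)

    return HaplotypeTable(sequences=reps, counts=counts, members=members, locality_counts=loc_counts)


def tn93_distance(a: np.ndarray, b: np.ndarray, freqs: np.ndarray) -> float:
    """Closed-form Tamura–Nei (1993) distance for one pair of byte arrays.

    ``freqs`` are empirical base frequencies (A, C, G, T).  Transitions are
    split into purine (A<->G) and pyrimidine (C<->T) classes.
    """
    resolved = np.isin(a, list(b"ACGT")) & np.isin(b, list(b"ACGT"))
    aa, bb = a[resolved], b[resolved]
    m = aa.size
    if m == 0:
        raise ValueError("no comparable sites for pair")
    diff = aa != bb
    is_a = lambda x: x == b"A"[0]  # noqa: E731
    is_g = lambda x: x == b"G"[0]  # noqa: E731
    is_c = lambda x: x == b"C"[0]  # noqa: E731
    is_t = lambda x: x == b"T"[0]  # noqa: E731
    p1 = np.sum(diff & ((is_a(aa) & is_g(bb)) | (is_g(aa) & is_a(bb)))) / m  # purine transitions
    p2 = np.sum(diff & ((is_c(aa) & is_t(bb)) | (is_t(aa) & is_c(bb)))) / m  # pyrimidine transitions
    purine_a = is_a(aa) | is_g(aa)
    purine_b = is_a(bb) | is_g(bb)
    q = np.sum(diff & (purine_a != purine_b)) / m  # transversions

    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    k1 = 2 * pa * pg / pr
    k2 = 2 * pc * pt / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    w1 = 1 - p1 / k1 - q / (2 * pr)
    w2 = 1 - p2 / k2 - q / (2 * py)
    w3 = 1 - q / (2 * pr * py)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise ValueError("TN93 log argument <= 0 (saturation); use p_distance instead")
    return float(-k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3))


def pairwise_distance(aln: Alignment, model: str = "raw_differences") -> DistanceMatrix:
    """All-pairs distances under ``raw_differences``, ``p_distance`` or ``TN93``.

    N and ``-`` are excluded pair-by-pair (pairwise deletion).  Raw
    differences are integer site counts; the other two models are in
    expected substitutions per site.
    """
    if model not in ("raw_differences", "p_distance", "TN93"):
        raise ValueError(f"unknown distance model: {model}")
    arr = aln.to_array()
    n = aln.n
    out = np.zeros((n, n), dtype=float)

    if model == "TN93":
        flat = arr.reshape(-1)
        counts = np.array([np.sum(flat == base) for base in b"ACGT"], dtype=float)
        if counts.sum() == 0:
            raise ValueError("no resolved bases in alignment")
        freqs = counts / counts.sum()
        for i, j in itertools.combinations(range(n), 2):
            m = int(np.sum(np.isin(arr[i], list(b"ACGT")) & np.isin(arr[j], list(b"ACGT"))))
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
            out[i, j] = out[j, i] = tn93_distance(arr[i], arr[j], freqs)
    else:
        resolved = np.isin(arr, list(b"ACGT"))
        both = resolved[:, None, :] & resolved[None, :, :]
        m_mat = both.sum(axis=2)
        d_mat = ((arr[:, None, :] != arr[None, :, :]) & both).sum(axis=2)
        iu = np.triu_indices(n, k=1)
        if np.any(m_mat[iu] == 0):
            i, j = next(zip(*[idx[m_mat[iu] == 0] for idx in iu]))
            raise ValueError(f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
        if model == "raw_differences":
            out = d_mat.astype(float)
        else:
            out = np.zeros_like(m_mat, dtype=float)
            np.divide(d_mat, m_mat, out=out, where=m_mat > 0)
        np.fill_diagonal(out, 0.0)

    units = "sites" if model == "raw_differences" else "substitutions/site"
    return DistanceMatrix(ids=list(aln.ids), values=out, model=model, units=units)
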