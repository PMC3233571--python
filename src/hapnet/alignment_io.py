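"""Reading, masking and collapsing aligned mtDNA control-region sequences.

This module turns a pre-aligned FASTA of hypervariable segment I (HVI)
sequences plus a sample annotation table into a :class:`HaplotypeTable`:

1. :func:`read_alignment` loads the gapped alignment (all records must have
   the same aligned length).
2. :func:`mask_columns` removes every alignment column that carries a gap in
   any sequence (indels are excluded from all downstream distance
   calculations) and, by default, every column carrying a non-ACGT ambiguity
   code.
3. :func:`read_annotation` loads per-sample region / domestic-wild metadata.
4. :func:`collapse_haplotypes` merges samples with identical retained-column
   sequences into haplotypes, tracking per-(region, status) individual counts.
5. :func:`crosstab_status` summarises haplotype sharing between domestic and
   wild samples.

Haplotype identifiers are assigned deterministically: samples are sorted
lexicographically by sample id and haplotypes numbered ``Hap1, Hap2, ...`` in
order of first appearance, so the labels do not depend on file order.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "REGIONS",
    "STATUSES",
    "RawAlignment",
    "AlignedSeqMatrix",
    "SampleRecord",
    "HaplotypeTable",
    "SharingSummary",
    "read_alignment",
    "mask_columns",
    "read_annotation",
    "collapse_haplotypes",
    "crosstab_status",
    "restrict_table",
    "write_haplotypes_fasta",
    "write_haplotype_table",
    "write_sharing_summary",
]

#: The 15 geographic region codes used to partition Asian pig samples:
#: the Tibetan highlands, South Asia, Yunnan, (Island) South East Asia, the
#: Pacific Islands, the upstream / middle-downstream Yangtze, South China,
#: Taiwan, the middle-upstream / downstream Yellow River, North East China,
#: Japan and Korea.
REGIONS: tuple[str, ...] = (
    "Tibet", "SA", "Yunnan", "SEA", "ISEA", "Pacific", "URYZ", "MDYZ",
    "SC", "Taiwan", "MUYR", "DRYR", "NEC", "Japan", "Korea",
)

STATUSES: tuple[str, ...] = ("domestic", "wild")

_BASES = frozenset("ACGT")

PathOrHandle = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class RawAlignment:
    """A gapped alignment exactly as read: ids in file order, sequences
    uppercased with ``U`` mapped to ``T``, gaps preserved."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class AlignedSeqMatrix:
    """A column-masked alignment: the matrix every distance is computed on.

    ``source_columns[j]`` is the 0-based index, in the original gapped
    alignment, of retained column ``j``.
    """

    sample_ids: tuple[str, ...]
    residues: tuple[str, ...]
    source_columns: tuple[int, ...]

    @property
    def columns(self) -> int:
        return len(self.source_columns)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        for sid, seq in zip(self.sample_ids, self.residues):
            if len(seq) != self.columns:
                raise ValueError(
                    f"sequence for {sid!r} has length {len(seq)}, "
                    f"expected {self.columns}"
                )

    def sequence_of(self, sample_id: str) -> str:
        return self.residues[self.sample_ids.index(sample_id)]


@dataclass(frozen=True)
class SampleRecord:
    """One annotated sample: region from the closed 15-code vocabulary and a
    domestic/wild status."""

    sample_id: str
    region: str
    status: str
    breed: str = ""
    haplogroup: str | None = None


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with per-(region, status) individual counts.

    ``haplotypes`` preserves the deterministic ``Hap<k>`` numbering;
    ``membership`` maps each haplotype to its sample ids; ``counts`` maps
    ``(haplotype_id, region, status)`` to the number of individuals.
    """

    haplotypes: list[tuple[str, str]]
    membership: dict[str, set[str]] = field(default_factory=dict)
    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def haplotype_ids(self) -> list[str]:
        return [h for h, _ in self.haplotypes]

    def sequence_of(self, hap_id: str) -> str:
        for h, s in self.haplotypes:
            if h == hap_id:
                return s
        raise KeyError(hap_id)

    def total_count(self, hap_id: str, status: str | None = None) -> int:
        return sum(
            n for (h, _r, s), n in self.counts.items()
            if h == hap_id and (status is None or s == status)
        )

    def regions_of(self, hap_id: str) -> set[str]:
        return {r for (h, r, _s), n in self.counts.items() if h == hap_id and n > 0}

    def statuses_of(self, hap_id: str) -> set[str]:
        return {s for (h, _r, s), n in self.counts.items() if h == hap_id and n > 0}

    def regions(self) -> list[str]:
        """Regions with at least one individual, in canonical order."""
        present = {r for (_h, r, _s), n in self.counts.items() if n > 0}
        known = [r for r in REGIONS if r in present]
        extra = sorted(present - set(REGIONS))
        return known + extra

    def n_samples(self) -> int:
        return sum(self.counts.values())

    def count(self, hap_id: str, region: str, status: str) -> int:
        return self.counts.get((hap_id, region, status), 0)


@dataclass(frozen=True)
class SharingSummary:
    """How many haplotypes are domestic-only, wild-only, or shared."""

    n_domestic_only: int
    n_wild_only: int
    n_shared: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_domestic_only + self.n_wild_only + self.n_shared != self.n_total:
            raise ValueError("sharing counts do not sum to the total")


def _as_handle(source: PathOrHandle) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r")
    return source


def read_alignment(fasta_source: PathOrHandle) -> RawAlignment:
    """Read a pre-aligned FASTA into a :class:`RawAlignment`.

    All records must share the same aligned length and carry unique ids.
    Sequences are uppercased and RNA ``U`` is mapped to ``T``; gap characters
    are preserved for :func:`mask_columns`.
    """
    handle = _as_handle(fasta_source)
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in ids:
            raise ValueError(f"duplicate sequence id {rec.id!r} in alignment")
        if seqs and len(seq) != len(seqs[0]):
            raise ValueError(
                f"alignment shape error: record {rec.id!r} has length "
                f"{len(seq)}, expected {len(seqs[0])}"
            )
        ids.append(rec.id)
        seqs.append(seq)
    if not ids:
        raise ValueError("empty alignment: no FASTA records found")
    return RawAlignment(ids=tuple(ids), seqs=tuple(seqs))


def mask_columns(
    raw: RawAlignment,
    drop_ambiguous_columns: bool = True,
    ambiguous_action: str = "drop_columns",
) -> AlignedSeqMatrix:
    """Apply the gap/ambiguity column-exclusion rule.

    Every column containing ``-`` in any sequence is removed. With
    ``drop_ambiguous_columns`` (default), every column containing a character
    outside ``ACGT`` is removed as well; with
    ``ambiguous_action="drop_sequences"`` the offending *sequences* are
    dropped instead and only gap columns of the survivors are excluded.

    ``source_columns`` of the result records, 0-based, where each retained
    column sat in the original alignment.
    """
    if ambiguous_action not in ("drop_columns", "drop_sequences"):
        raise ValueError("ambiguous_action must be 'drop_columns' or 'drop_sequences'")
    ids = list(raw.ids)
    arr = np.array([list(s) for s in raw.seqs], dtype="U1")
    if drop_ambiguous_columns and ambiguous_action == "drop_sequences":
        bad_rows = (~np.isin(arr, list(_BASES)) & (arr != "-")).any(axis=1)
        if bad_rows.all():
            raise ValueError("all sequences contain ambiguity characters")
        if bad_rows.any():
            dropped = [i for i, b in zip(ids, bad_rows) if b]
            warnings.warn(f"dropped {len(dropped)} sequences with ambiguity codes: "
                          f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
        arr = arr[~bad_rows]
        ids = [i for i, b in zip(ids, bad_rows) if not b]
    keep = ~(arr == "-").any(axis=0)
    if drop_ambiguous_columns and ambiguous_action == "drop_columns":
        keep &= np.isin(arr, list(_BASES)).all(axis=0)
    else:
        # gap-only policy still cannot leave non-nucleotide junk behind a '-'
        keep &= (arr != "-").all(axis=0)
    if not keep.any():
        raise ValueError(
            "no alignment columns survive gap/ambiguity masking; inspect the "
            "alignment for pervasive gaps or ambiguity codes"
        )
    kept = arr[:, keep]
    residues = tuple("".join(row) for row in kept)
    source_columns = tuple(int(j) for j in np.nonzero(keep)[0])
    return AlignedSeqMatrix(
        sample_ids=tuple(ids), residues=residues, source_columns=source_columns
    )


def read_annotation(
    tsv_source: PathOrHandle,
    valid_regions: Sequence[str] = REGIONS,
) -> list[SampleRecord]:
    """Read the sample annotation TSV (header ``sample_id, region, status,
    breed[, haplogroup]``) into :class:`SampleRecord` objects.

    Region codes outside ``valid_regions`` and statuses outside
    ``{domestic, wild}`` are rejected with an error naming the valid values.
    """
    handle = _as_handle(tsv_source)
    text = handle.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty annotation file")
    header = [c.strip() for c in lines[0].split("\t")]
    required = ("sample_id", "region", "status")
    for col in required:
        if col not in header:
            raise ValueError(f"annotation header missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    valid = set(valid_regions)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split("\t")]
        row = {c: (cells[i] if i < len(cells) else "") for c, i in idx.items()}
        region, status = row["region"], row["status"]
        if region not in valid:
            raise ValueError(
                f"line {lineno}: unknown region {region!r}; valid codes: "
                f"{', '.join(sorted(valid))}"
            )
        if status not in STATUSES:
            raise ValueError(
                f"line {lineno}: status {status!r} must be one of {STATUSES}"
            )
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"line {lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                region=region,
                status=status,
                breed=row.get("breed", ""),
                haplogroup=row.get("haplogroup") or None,
            )
        )
    return records


def collapse_haplotypes(
    matrix: AlignedSeqMatrix,
    annotations: Iterable[SampleRecord],
) -> HaplotypeTable:
    """Collapse identical retained-column sequences into haplotypes.

    Every sample in ``matrix`` must carry exactly one annotation; annotation
    rows whose sample id is absent from the alignment are ignored with a
    warning. Haplotype ids follow the deterministic naming rule described in
    the module docstring.
    """
    ann = {}
    for rec in annotations:
        ann[rec.sample_id] = rec
    extra = sorted(set(ann) - set(matrix.sample_ids))
    if extra:
        warnings.warn(
            f"{len(extra)} annotated samples absent from the alignment: "
            f"{extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    missing = [sid for sid in matrix.sample_ids if sid not in ann]
    if missing:
        raise ValueError(f"unannotated sample(s) in alignment: {missing[:5]}")

    seq_by_sample = dict(zip(matrix.sample_ids, matrix.residues))
    order = sorted(matrix.sample_ids)
    hap_of_seq: dict[str, str] = {}
    haplotypes: list[tuple[str, str]] = []
    membership: dict[str, set[str]] = {}
    counts: dict[tuple[str, str, str], int] = {}
    for sid in order:
        seq = seq_by_sample[sid]
        hap = hap_of_seq.get(seq)
        if hap is None:
            hap = f"Hap{len(haplotypes) + 1}"
            hap_of_seq[seq] = hap
            haplotypes.append((hap, seq))
            membership[hap] = set()
        membership[hap].add(sid)
        rec = ann[sid]
        key = (hap, rec.region, rec.status)
        counts[key] = counts.get(key, 0) + 1
    return HaplotypeTable(haplotypes=haplotypes, membership=membership, counts=counts)


def crosstab_status(table: HaplotypeTable) -> SharingSummary:
    """Classify every haplotype as domestic-only, wild-only or shared."""
    if not table.haplotypes:
        raise ValueError("empty haplotype table")
    dom_only = wild_only = shared = 0
    for hap in table.haplotype_ids:
        st = table.statuses_of(hap)
        if st == {"domestic"}:
            dom_only += 1
        elif st == {"wild"}:
            wild_only += 1
        else:
            shared += 1
    return SharingSummary(
        n_domestic_only=dom_only,
        n_wild_only=wild_only,
        n_shared=shared,
        n_total=len(table.haplotypes),
    )


def restrict_table(table: HaplotypeTable, hap_ids: Iterable[str]) -> HaplotypeTable:
    """A sub-table containing only the given haplotypes (original ids and
    counts kept), e.g. to restrict the diversity tabulation to one subgroup."""
    keep = set(hap_ids)
    unknown = keep - set(table.haplotype_ids)
    if unknown:
        raise KeyError(f"unknown haplotype id(s): {sorted(unknown)[:5]}")
    return HaplotypeTable(
        haplotypes=[(h, s) for h, s in table.haplotypes if h in keep],
        membership={h: set(m) for h, m in table.membership.items() if h in keep},
        counts={k: n for k, n in table.counts.items() if k[0] in keep},
    )


def write_haplotypes_fasta(table: HaplotypeTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for hap, seq in table.haplotypes:
            fh.write(f">{hap}\n{seq}\n")
    return path


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("haplotype_id\tregion\tstatus\tcount\n")
        for hap in table.haplotype_ids:
            for (h, region, status), n in sorted(table.counts.items()):
                if h == hap and n > 0:
                    fh.write(f"{hap}\t{region}\t{status}\t{n}\n")
    return path


def write_sharing_summary(summary: SharingSummary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("n_domestic_only\tn_wild_only\tn_shared\tn_total\n")
        fh.write(
            f"{summary.n_domestic_only}\t{summary.n_wild_only}\t"
            f"{summary.n_shared}\t{summary.n_total}\n"
        )
    return path
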