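"""Data types and on-disk formats.

All coordinates are 0-based half-open (BED convention). CpGs are
destranded: counts from both strands are attributed to the position of
the forward-strand C, so a CpG "site" is a single position and a region
of length one has ``end == start + 1``.

Formats handled here:

* methylation bedGraph (MethylDackel extractor dialect):
  ``contig  start  end  percent  n_meth  n_unmeth`` — the percent column
  is ignored on input and recomputed on demand;
* BED6+ for DMRs (name, score=round(1000*|diff|), then n_cpg, mean_a,
  mean_b, diff, mean_cov, p, q);
* TSVs for gene models, marker panels, amplicon per-read tables and
  screening cohorts.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file does not conform to its format."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    label: str = ""
    klass: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene reduced to what promoter annotation needs."""

    gene_id: str
    contig: str
    tss: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class MethylomeTrack:
    """Per-CpG methylated/unmethylated counts for one sample.

    Sites are stored as parallel arrays sorted by (contig, position);
    positions are strictly increasing within each contig. Depth-0 sites
    are carried (level is NaN there) so that the site universe is shared
    across samples.
    """

    sample_id: str
    contigs: np.ndarray  # str array, one entry per site
    pos: np.ndarray  # int64
    n_meth: np.ndarray  # int64
    n_unmeth: np.ndarray  # int64
    _blocks: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.n_meth = np.asarray(self.n_meth, dtype=np.int64)
        self.n_unmeth = np.asarray(self.n_unmeth, dtype=np.int64)
        n = len(self.pos)
        if not (len(self.contigs) == len(self.n_meth) == len(self.n_unmeth) == n):
            raise ValueError("site arrays must have equal length")
        if np.any(self.n_meth < 0) or np.any(self.n_unmeth < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.pos < 0):
            raise ValueError("positions must be non-negative")
        # contiguous per-contig blocks with strictly increasing positions
        self._blocks = {}
        i = 0
        while i < n:
            c = self.contigs[i]
            j = i
            while j < n and self.contigs[j] == c:
                j += 1
            if c in self._blocks:
                raise ValueError(f"contig {c} appears in non-contiguous blocks")
            if np.any(np.diff(self.pos[i:j]) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
            self._blocks[c] = (i, j)
            i = j

    # -- derived quantities -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def depth(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def levels(self) -> np.ndarray:
        """Per-site methylation level beta; NaN where depth is 0."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.n_meth / d, np.nan)

    def contig_block(self, contig: str) -> tuple[int, int]:
        """(start, end) index range of a contig's sites; (0, 0) if absent."""
        return self._blocks.get(contig, (0, 0))

    def region_slice(self, region: Region) -> slice:
        """Index slice of sites falling inside ``region``."""
        lo, hi = self.contig_block(region.contig)
        p = self.pos[lo:hi]
        a = int(np.searchsorted(p, region.start, side="left"))
        b = int(np.searchsorted(p, region.end, side="left"))
        return slice(lo + a, lo + b)

    def same_sites(self, other: "MethylomeTrack") -> bool:
        return (
            self.n_sites == other.n_sites
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.contigs, other.contigs)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contigs,
                "start": self.pos,
                "end": self.pos + 1,
                "percent": np.round(100 * np.nan_to_num(self.levels), 2),
                "n_meth": self.n_meth,
                "n_unmeth": self.n_unmeth,
            }
        )


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

STATE_METH = 1
STATE_UNMETH = 0
STATE_MISSING = -1

_STATE_CHARS = {"M": STATE_METH, "U": STATE_UNMETH, ".": STATE_MISSING}
_CHAR_STATES = {v: k for k, v in _STATE_CHARS.items()}


@dataclass
class AmpliconReadSet:
    """Per-read CpG states over one deep-bisulfite amplicon.

    ``states`` is an (n_reads, k) int8 matrix over {1 methylated,
    0 unmethylated, -1 missing}. ``masked`` holds 0-based CpG column
    indices excluded from all methylation summaries (CpG-SNPs);
    ``snp_offset`` is the column in the read carrying the allele base,
    recorded per read in ``allele``.
    """

    locus_id: str
    states: np.ndarray
    allele: np.ndarray  # one base per read, 'N' if unknown
    read_ids: np.ndarray
    masked: frozenset = frozenset()
    snp_offset: Optional[int] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (reads x CpGs) matrix")
        self.allele = np.asarray(self.allele, dtype=object)
        self.read_ids = np.asarray(self.read_ids, dtype=object)
        if len(self.allele) != self.n_reads or len(self.read_ids) != self.n_reads:
            raise ValueError("per-read arrays must match the number of reads")
        self.masked = frozenset(int(i) for i in self.masked)
        if any(i < 0 or i >= self.k for i in self.masked):
            raise ValueError("masked index out of range")

    @property
    def n_reads(self) -> int:
        return self.states.shape[0]

    @property
    def k(self) -> int:
        return self.states.shape[1]

    @property
    def unmasked_columns(self) -> np.ndarray:
        return np.array([j for j in range(self.k) if j not in self.masked], dtype=int)

    def subset(self, row_idx: np.ndarray) -> "AmpliconReadSet":
        return AmpliconReadSet(
            locus_id=self.locus_id,
            states=self.states[row_idx],
            allele=self.allele[row_idx],
            read_ids=self.read_ids[row_idx],
            masked=self.masked,
            snp_offset=self.snp_offset,
        )


# ---------------------------------------------------------------------------
# bedGraph methylation I/O
# ---------------------------------------------------------------------------


def read_methylation_bedgraph(path, sample_id: str) -> MethylomeTrack:
    """Read a 6-column methylation bedGraph into a MethylomeTrack.

    Columns: contig, start, end, percent, n_meth, n_unmeth. The percent
    column is ignored. Lines starting with ``track`` or ``#`` are
    skipped. Input must be sorted (positions strictly increasing within
    each contiguous contig block); malformed lines raise ParseError with
    the line number.
    """
    contigs, pos, meth, unmeth = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            try:
                start = int(parts[1])
                end = int(parts[2])
                nm = int(parts[4])
                nu = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if end != start + 1:
                raise ParseError(
                    f"{path}: line {lineno}: CpG record must span one base (end = start + 1)"
                )
            if nm < 0 or nu < 0 or start < 0:
                raise ParseError(f"{path}: line {lineno}: negative value")
            contigs.append(parts[0])
            pos.append(start)
            meth.append(nm)
            unmeth.append(nu)
    try:
        return MethylomeTrack(
            sample_id=sample_id,
            contigs=np.array(contigs, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            n_meth=np.array(meth, dtype=np.int64),
            n_unmeth=np.array(unmeth, dtype=np.int64),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: unsorted or invalid input: {exc}") from None


def write_methylation_bedgraph(track: MethylomeTrack, path) -> None:
    track.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DMR BED6+ I/O (record type lives in dmr.py; handled duck-typed here)
# ---------------------------------------------------------------------------

_DMR_HEADER = [
    "#contig",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "n_cpg",
    "mean_a",
    "mean_b",
    "diff",
    "mean_cov",
    "p",
    "q",
]


def write_dmrs_bed(dmrs: Sequence, path) -> None:
    """Write DMRs as BED6+ with a commented header; lossless round-trip."""
    rows = []
    for d in dmrs:
        rows.append(
            [
                d.region.contig,
                d.region.start,
                d.region.end,
                d.region.label or ".",
                int(round(1000 * abs(d.diff))),
                ".",
                d.n_cpg,
                repr(float(d.mean_a)),
                repr(float(d.mean_b)),
                repr(float(d.diff)),
                repr(float(np.mean(d.mean_cov_per_sample))),
                repr(float(d.p)),
                repr(float(d.q)),
            ]
        )
    with open(path, "w") as fh:
        fh.write("\t".join(_DMR_HEADER) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_dmrs_bed(path) -> list:
    """Read DMRs written by :func:`write_dmrs_bed`."""
    from .dmr import DMR  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) != len(_DMR_HEADER):
                raise ParseError(f"{path}: line {lineno}: expected {len(_DMR_HEADER)} columns")
            try:
                diff = float(p[9])
                out.append(
                    DMR(
                        region=Region(p[0], int(p[1]), int(p[2]), label="" if p[3] == "." else p[3]),
                        n_cpg=int(p[6]),
                        mean_a=float(p[7]),
                        mean_b=float(p[8]),
                        diff=diff,
                        mean_cov_per_sample=[float(p[10])],
                        p=float(p[11]),
                        q=float(p[12]),
                        direction="a_hyper" if diff > 0 else "b_hyper",
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# regions / gene models / marker panels / cohorts
# ---------------------------------------------------------------------------


def write_regions_bed(regions: Iterable[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label or '.'}\t{r.klass or '.'}\n")


def read_regions_bed(path) -> list[Region]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            label = p[3] if len(p) > 3 and p[3] != "." else ""
            klass = p[4] if len(p) > 4 and p[4] != "." else ""
            try:
                out.append(Region(p[0], int(p[1]), int(p[2]), label=label, klass=klass))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_gene_models_tsv(genes: Iterable[GeneModel], path) -> None:
    df = pd.DataFrame([dataclasses.asdict(g) for g in genes])
    df.to_csv(path, sep="\t", index=False)


def read_gene_models_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    required = {"gene_id", "contig", "tss", "strand", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneModel(r.gene_id, r.contig, int(r.tss), r.strand, r.biotype)
        for r in df.itertuples(index=False)
    ]


def read_amplicon_reads_tsv(path) -> AmpliconReadSet:
    """Read a per-read amplicon table.

    Expected columns (tab-separated, with header): ``read_id``,
    ``allele_base``, ``states`` where states is a string over
    {M, U, .} — '.' marks a missing call. Optional ``# locus_id=...``,
    ``# masked=...`` (comma-separated indices), ``# snp_offset=...``
    comment lines carry set-level metadata.
    """
    locus_id, masked, snp_offset = "", frozenset(), None
    read_ids, alleles, rows = [], [], []
    k = None
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                meta = line.lstrip("# ").split("=", 1)
                if len(meta) == 2:
                    key, val = meta[0].strip(), meta[1].strip()
                    if key == "locus_id":
                        locus_id = val
                    elif key == "masked":
                        masked = frozenset(int(x) for x in val.split(",") if x != "")
                    elif key == "snp_offset":
                        snp_offset = int(val)
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[:3] != ["read_id", "allele_base", "states"]:
                    raise ParseError(f"{path}: line {lineno}: unexpected header {header}")
                continue
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            rid, base, states = parts
            if k is None:
                k = len(states)
            elif len(states) != k:
                raise ParseError(
                    f"{path}: line {lineno}: ragged state string "
                    f"(length {len(states)}, expected {k})"
                )
            try:
                rows.append([_STATE_CHARS[c] for c in states])
            except KeyError as exc:
                raise ParseError(f"{path}: line {lineno}: bad state character {exc}") from None
            read_ids.append(rid)
            alleles.append(base)
    if k is None:
        raise ParseError(f"{path}: no reads")
    return AmpliconReadSet(
        locus_id=locus_id,
        states=np.array(rows, dtype=np.int8),
        allele=np.array(alleles, dtype=object),
        read_ids=np.array(read_ids, dtype=object),
        masked=masked,
        snp_offset=snp_offset,
    )


def write_amplicon_reads_tsv(rs: AmpliconReadSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# locus_id={rs.locus_id}\n")
        fh.write("# masked=" + ",".join(str(i) for i in sorted(rs.masked)) + "\n")
        if rs.snp_offset is not None:
            fh.write(f"# snp_offset={rs.snp_offset}\n")
        fh.write("read_id\tallele_base\tstates\n")
        for i in range(rs.n_reads):
            s = "".join(_CHAR_STATES[int(v)] for v in rs.states[i])
            fh.write(f"{rs.read_ids[i]}\t{rs.allele[i]}\t{s}\n")


def write_marker_panel_tsv(panel, path) -> None:
    from .purity import Marker  # noqa: F401  (documentation of the record type)

    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tlabel\tklass\texpected_sperm\texpected_soma\n")
        for m in panel:
            r = m.region
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.label or '.'}\t{m.klass}\t"
                f"{m.expected_sperm!r}\t{m.expected_soma!r}\n"
            )


def read_marker_panel_tsv(path) -> list:
    from .purity import Marker

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["contig", "start", "end"]:
            raise ParseError(f"{path}: unexpected marker panel header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            if len(p) != 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 columns")
            try:
                out.append(
                    Marker(
                        region=Region(p[0], int(p[1]), int(p[2]), label="" if p[3] == "." else p[3]),
                        klass=p[4],
                        expected_sperm=float(p[5]),
                        expected_soma=float(p[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_screen_cohort_tsv(path) -> pd.DataFrame:
    """Read a screening cohort table.

    Required columns: sample_id, diagnosis (normo|oligo), mean_mest,
    mean_h19; optional: mean_xist, mean_ddx4, genotype.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "diagnosis", "mean_mest", "mean_h19"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["diagnosis"].unique()) - {"normo", "oligo"}
    if bad:
        raise ParseError(f"{path}: unknown diagnosis values {sorted(bad)}")
    return df
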