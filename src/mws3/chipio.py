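"""Read-structure parsing, barcode correction and on-disk formats.

Microwell-seq3 reads carry three identity layers: a 10-nt preindex (BC#1,
introduced in-plate before pooling), an 18-nt combinatorial bead barcode
(BC#2, three split-pool 6-nt segments) and a molecule tag.  In RNA mode the
molecule tag is a 17-nt random oligonucleotide whose leading bases double as
the UMI; in ATAC mode molecules are identified by aligned fragment
coordinates, with an optional 14-nt spike-in oligo library marking
co-residence of beads in one microwell.

This module knows how to slice those fields out of raw read pairs, how to
snap observed barcodes back onto their whitelists, and how to read and write
every plain-text format the rest of the package exchanges (FASTQ, tagged-read
TSV, fragments TSV, MatrixMarket matrices, BED4 cytobands, JSON reports).
"""

from __future__ import annotations

import functools
import gzip
import itertools
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"

#: column order of the tagged-read TSV exchanged between pipeline stages
TAGGED_COLUMNS = [
    "bead_barcode",
    "preindex",
    "umi",
    "feature_tag",
    "chrom",
    "start",
    "end",
    "spikein_tag",
    "annotation",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


class FormatError(ValueError):
    """Malformed on-disk record; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Read layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadLayout:
    """Positions of barcode/tag fields within a read pair.

    RNA read 1 opens with the molecule-tag region: ``feature_tag_len`` random
    bases of which the first ``umi_len`` serve as the UMI.  The bead barcode
    follows the tag region, and read 2 opens with the preindex.  ATAC read 1
    opens with the bead barcode immediately followed by the preindex; the
    molecule identity comes from alignment, not from the read sequence.
    """

    assay: str = "rna"
    umi_len: int = 6
    feature_tag_len: int = 17
    bead_barcode_len: int = 18
    bead_segments: int = 3
    preindex_len: int = 10

    def __post_init__(self):
        if self.assay not in ("rna", "atac"):
            raise ValueError(f"unknown assay {self.assay!r}")
        for name in ("bead_barcode_len", "preindex_len", "bead_segments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.assay == "rna":
            if self.umi_len <= 0 or self.feature_tag_len <= 0:
                raise ValueError("umi_len and feature_tag_len must be positive")
            if self.umi_len > self.feature_tag_len:
                raise ValueError("umi_len cannot exceed feature_tag_len")
        if self.bead_barcode_len % self.bead_segments:
            raise ValueError("bead_barcode_len must divide into equal segments")

    @property
    def segment_len(self) -> int:
        return self.bead_barcode_len // self.bead_segments

    @property
    def read1_min_len(self) -> int:
        if self.assay == "rna":
            return self.feature_tag_len + self.bead_barcode_len
        return self.bead_barcode_len + self.preindex_len

    @property
    def read2_min_len(self) -> int:
        return self.preindex_len if self.assay == "rna" else 0

    @classmethod
    def rna(cls, **kw) -> "ReadLayout":
        return cls(assay="rna", **kw)

    @classmethod
    def atac(cls, **kw) -> "ReadLayout":
        return cls(assay="atac", **kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ReadLayout":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Tagged reads
# ---------------------------------------------------------------------------


@dataclass
class TaggedRead:
    """One sequenced molecule after field extraction.

    Exactly one of ``feature_tag`` (RNA), ``fragment`` (ATAC genomic) or
    ``spikein_tag`` (ATAC spike-in oligo) identifies the molecule.
    Fragments are (chrom, start, end), 0-based half-open.
    """

    bead_barcode: str
    preindex: str
    umi: str = ""
    feature_tag: str = ""
    fragment: Optional[tuple] = None
    spikein_tag: Optional[str] = None
    annotation: Optional[str] = None

    def __post_init__(self):
        populated = sum(
            [bool(self.feature_tag), self.fragment is not None, self.spikein_tag is not None]
        )
        if populated > 1:
            raise ValueError("feature_tag, fragment and spikein_tag are mutually exclusive")


def extract_tags(read1: str, read2: str, layout: ReadLayout) -> Optional[TaggedRead]:
    """Slice barcode/tag fields from a raw read pair.

    Returns ``None`` when a mate is too short to contain the required span;
    callers count and skip such reads.
    """
    if not read1 or (layout.assay == "rna" and not read2):
        return None
    if len(read1) < layout.read1_min_len or len(read2 or "") < layout.read2_min_len:
        return None
    if layout.assay == "rna":
        tag = read1[: layout.feature_tag_len]
        bead = read1[layout.feature_tag_len : layout.feature_tag_len + layout.bead_barcode_len]
        return TaggedRead(
            bead_barcode=bead,
            preindex=read2[: layout.preindex_len],
            umi=tag[: layout.umi_len],
            feature_tag=tag,
        )
    bead = read1[: layout.bead_barcode_len]
    pre = read1[layout.bead_barcode_len : layout.bead_barcode_len + layout.preindex_len]
    return TaggedRead(bead_barcode=bead, preindex=pre)


# ---------------------------------------------------------------------------
# Whitelists and barcode correction
# ---------------------------------------------------------------------------


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def correct_barcode(
    observed: str, whitelist_segment: Sequence[str], max_hamming: int = 1
) -> Optional[str]:
    """Snap one observed k-mer onto a whitelist segment.

    Returns the unique entry within ``max_hamming`` mismatches, the entry
    itself on an exact match, or ``None`` when no entry — or more than one
    equidistant entry — qualifies.
    """
    entries = whitelist_segment
    if not entries:
        return None
    k = len(entries[0])
    if len(observed) != k:
        raise ValueError(f"observed barcode length {len(observed)} != whitelist length {k}")
    if observed in set(entries):
        return observed
    best, best_d, ties = None, max_hamming + 1, 0
    for entry in entries:
        d = hamming(observed, entry)
        if d < best_d:
            best, best_d, ties = entry, d, 1
        elif d == best_d:
            ties += 1
    if best_d <= max_hamming and ties == 1:
        return best
    return None


@dataclass
class Whitelist:
    """Ordered list of allowed k-mers per barcode segment.

    A bead whitelist carries three 96-entry 6-mer segments; a preindex
    whitelist carries one 384-entry 10-mer segment.  Composite barcodes are
    corrected segment-wise, each segment against its own entry list.
    """

    segments: list
    max_hamming: int = 1
    _sets: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("whitelist needs at least one segment")
        for seg in self.segments:
            if not seg:
                raise ValueError("empty whitelist segment")
            lens = {len(e) for e in seg}
            if len(lens) != 1:
                raise ValueError("entries within a segment must share one length")
            if len(set(seg)) != len(seg):
                raise ValueError("duplicate whitelist entries")
        self._sets = [set(seg) for seg in self.segments]

    @property
    def total_len(self) -> int:
        return sum(len(seg[0]) for seg in self.segments)

    def correct(self, observed: str) -> Optional[str]:
        """Correct a (possibly composite) barcode; ``None`` drops the read."""
        if len(observed) != self.total_len:
            raise ValueError("observed barcode has wrong length")
        out, pos = [], 0
        for seg, members in zip(self.segments, self._sets):
            k = len(seg[0])
            piece = observed[pos : pos + k]
            pos += k
            if piece in members:  # exact hit, skip the scan
                out.append(piece)
                continue
            fixed = correct_barcode(piece, seg, self.max_hamming)
            if fixed is None:
                return None
            out.append(fixed)
        return "".join(out)

    def save(self, directory, prefix: str = "segment") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, seg in enumerate(self.segments, start=1):
            (directory / f"{prefix}_{i}.txt").write_text("\n".join(seg) + "\n")

    @classmethod
    def load(cls, directory, prefix: str = "segment", max_hamming: int = 1) -> "Whitelist":
        directory = Path(directory)
        paths = sorted(directory.glob(f"{prefix}_*.txt"))
        if not paths:
            raise FileNotFoundError(f"no {prefix}_*.txt files under {directory}")
        segments = [p.read_text().split() for p in paths]
        return cls(segments=segments, max_hamming=max_hamming)


# Base code for 6-mer segments: a greedy Hamming-distance->=3 code over the
# full 6-mer space, grown in a fixed pseudorandom order.  The ordering seed
# is a structural constant (it determines which 98-word code is found), not
# an experiment seed; per-experiment whitelists are drawn from this base.
_BASE_ORDER_SEED = 169


@functools.lru_cache(maxsize=None)
def _base_segment_code(k: int = 6, min_dist: int = 3) -> tuple:
    words = np.array(list(itertools.product(range(4), repeat=k)), dtype=np.int8)
    order = np.random.default_rng(_BASE_ORDER_SEED).permutation(len(words))
    code: list[np.ndarray] = []
    arr = None
    for i in order:
        w = words[i]
        if arr is None or ((arr != w).sum(axis=1) >= min_dist).all():
            code.append(w)
            arr = np.asarray(code)
    return tuple("".join(ALPHABET[b] for b in w) for w in code)


def build_bead_whitelist(seed: int, n_segments: int = 3, entries_per_segment: int = 96) -> Whitelist:
    """Three 96-entry 6-mer segments with pairwise Hamming distance >= 3.

    Entries are drawn per segment from a fixed base code so that one
    mismatch anywhere in the 18-mer is always uniquely correctable.
    """
    base = _base_segment_code()
    if entries_per_segment > len(base):
        raise ValueError(f"at most {len(base)} entries per 6-mer segment available")
    rng = np.random.default_rng(seed)
    segments = []
    for _ in range(n_segments):
        idx = rng.choice(len(base), size=entries_per_segment, replace=False)
        segments.append([base[i] for i in idx])
    return Whitelist(segments=segments)


def build_preindex_whitelist(
    seed: int, n_entries: int = 384, length: int = 10, min_dist: int = 3
) -> Whitelist:
    """One segment of random 10-mers kept pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    arr = None
    attempts = 0
    while len(chosen) < n_entries:
        attempts += 1
        if attempts > 200 * n_entries:
            raise RuntimeError("preindex whitelist sampling did not converge")
        w = rng.integers(0, 4, size=length).astype(np.int8)
        if arr is None or ((arr != w).sum(axis=1) >= min_dist).all():
            chosen.append(w)
            arr = np.asarray(chosen)
    entries = ["".join(ALPHABET[b] for b in w) for w in chosen]
    return Whitelist(segments=[entries])


def correct_tagged_reads(
    reads: pd.DataFrame, bead_whitelist: Whitelist, preindex_whitelist: Whitelist
) -> tuple[pd.DataFrame, dict]:
    """Whitelist-correct the barcode columns of a tagged-read table.

    Reads whose bead barcode or preindex cannot be corrected unambiguously
    are dropped; the report counts them.  Correction is memoised per
    distinct observed barcode, so cost scales with the number of distinct
    barcodes rather than reads.
    """
    report = {"input_reads": int(len(reads))}
    bead_map = {obs: bead_whitelist.correct(obs) for obs in reads["bead_barcode"].unique()}
    pre_map = {obs: preindex_whitelist.correct(obs) for obs in reads["preindex"].unique()}
    bead = reads["bead_barcode"].map(bead_map)
    pre = reads["preindex"].map(pre_map)
    keep = bead.notna() & pre.notna()
    out = reads.loc[keep].copy()
    out["bead_barcode"] = bead[keep]
    out["preindex"] = pre[keep]
    report["dropped_bead_barcode"] = int((~bead.notna()).sum())
    report["dropped_preindex"] = int((bead.notna() & ~pre.notna()).sum())
    report["output_reads"] = int(len(out))
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        if "r" in mode:
            return gzip.open(path, mode)
        # mtime=0 keeps gzip output byte-identical across reruns
        return gzip.GzipFile(path, mode.replace("t", "b"), mtime=0)
    return open(path, mode)


def read_fastq(path) -> Iterator[SeqRecord]:
    with _open_text(path) as fh:
        if isinstance(fh, gzip.GzipFile):  # binary handle needs text wrapping
            import io

            fh = io.TextIOWrapper(fh)
        yield from SeqIO.parse(fh, "fastq")


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    path = os.fspath(path)
    n = 0
    if path.endswith(".gz"):
        import io

        with gzip.GzipFile(path, "wb", mtime=0) as raw:
            with io.TextIOWrapper(raw) as fh:
                n = SeqIO.write(records, fh, "fastq")
    else:
        with open(path, "w") as fh:
            n = SeqIO.write(records, fh, "fastq")
    return n


def make_fastq_record(read_id: str, sequence: str, description: str = "") -> SeqRecord:
    rec = SeqRecord(Seq(sequence), id=read_id, description=description)
    rec.letter_annotations["phred_quality"] = [40] * len(sequence)
    return rec


# ---------------------------------------------------------------------------
# Tagged-read TSV
# ---------------------------------------------------------------------------


def write_tagged(reads: pd.DataFrame, path) -> None:
    df = reads.reindex(columns=TAGGED_COLUMNS)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_tagged(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: "string" for c in TAGGED_COLUMNS if c not in ("start", "end")},
        keep_default_na=False,
    )
    missing = [c for c in TAGGED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"tagged file missing columns {missing}", line=1)
    for col in ("start", "end"):
        s = df[col].astype(object)
        s[s == ""] = pd.NA
        df[col] = pd.to_numeric(s, errors="raise").astype("Int64")
    for col in df.columns:
        if df[col].dtype == "string":
            df[col] = df[col].astype(object)
    return df


# ---------------------------------------------------------------------------
# Fragments TSV (chrom, start, end, barcode, count; 0-based half-open)
# ---------------------------------------------------------------------------


def write_fragments(fragments: pd.DataFrame, path) -> None:
    df = fragments.reindex(columns=FRAGMENT_COLUMNS)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_fragments(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        if isinstance(fh, gzip.GzipFile):
            import io

            fh = io.TextIOWrapper(fh)
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"expected 5 tab-separated fields, got {len(parts)}", lineno)
            chrom, start, end, barcode, count = parts
            try:
                start_i, end_i, count_i = int(start), int(end), int(count)
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate or count: {exc}", lineno) from exc
            if start_i < 0 or end_i <= start_i or count_i < 1:
                raise FormatError("require 0 <= start < end and count >= 1", lineno)
            rows.append((chrom, start_i, end_i, barcode, count_i))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Count matrices (MatrixMarket + label files)
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Feature x cell counts with per-cell metadata.

    ``matrix`` is features (rows) by cells (columns), non-negative.  ``obs``
    holds per-cell metadata (total counts, genes detected, TSS score when
    provided, sample, per-species counts) indexed by cell barcode.
    """

    features: list
    cells: list
    matrix: scipy.sparse.csr_matrix
    obs: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.matrix = scipy.sparse.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.features), len(self.cells)):
            raise ValueError("matrix shape does not match label lengths")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cells, name="cell"))
        else:
            self.obs = self.obs.reindex(self.cells)

    @property
    def shape(self):
        return self.matrix.shape

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def features_detected(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.matrix.T.tocsr(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(self.features, name="feature")),
        )

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), scipy.sparse.coo_matrix(self.matrix))
        (directory / "features.tsv").write_text("\n".join(map(str, self.features)) + "\n")
        (directory / "barcodes.tsv").write_text("\n".join(map(str, self.cells)) + "\n")
        if len(self.obs.columns):
            self.obs.to_csv(directory / "obs.tsv", sep="\t")

    @classmethod
    def read(cls, directory) -> "CountMatrix":
        directory = Path(directory)
        matrix = scipy.sparse.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
        features = (directory / "features.tsv").read_text().split()
        cells = (directory / "barcodes.tsv").read_text().split()
        obs = None
        if (directory / "obs.tsv").exists():
            obs = pd.read_csv(directory / "obs.tsv", sep="\t", index_col=0)
        return cls(features=features, cells=cells, matrix=matrix, obs=obs)


# ---------------------------------------------------------------------------
# BED4 cytobands and JSON
# ---------------------------------------------------------------------------


def read_bed4(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"expected >=4 BED fields, got {len(parts)}", lineno)
            chrom, start, end, name = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", lineno) from exc
            if start_i < 0 or end_i <= start_i:
                raise FormatError("require 0 <= start < end", lineno)
            rows.append((chrom, start_i, end_i, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed4(regions: pd.DataFrame, path) -> None:
    regions[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", index=False, header=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
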