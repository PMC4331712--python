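"""Curated interaction tables: parsing, merging, and promoter-window inference.

This module owns the coordinate conventions of the package.  Everything
internal is 1-based, closed intervals (the convention of locus strings and
GFF3); BED input is converted from 0-based half-open at the I/O boundary.

Two kinds of directed edges are handled:

``tf_mirna``
    a transcription factor regulating a miRNA gene, either curated
    (TransmiR-style TSV) or inferred from ChIP-Seq peaks falling in the
    miRNA's promoter window.
``mti``
    an experimentally supported, repressive miRNA -> gene edge
    (miRTarBase/TarBase/starBase-style TSV).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ParseError, UnmappedNameWarning

_LOCUS_RE = re.compile(
    r"^\s*(?P<chrom>[A-Za-z0-9_.]+)\s*:\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*:\s*(?P<strand>[+-])\s*$"
)

_SPECIES_PREFIX_RE = re.compile(r"^(?:[a-z]{3,4})-(?=miR|let|mir)", re.IGNORECASE)


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA gene locus: 1-based closed genomic interval plus strand."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ParseError("miRNA locus requires a non-empty name")
        if self.strand not in ("+", "-"):
            raise ParseError(f"invalid strand {self.strand!r} for {self.name}")
        if self.start > self.end:
            raise ParseError(
                f"locus start > end ({self.start} > {self.end}) for {self.name}"
            )
        if self.start < 1:
            raise ParseError(f"locus start must be >= 1, got {self.start}")

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end of the locus (strand aware)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PromoterConfig:
    """Promoter window extent around a locus 5' end (defaults: -5 kb / +1 kb)."""

    upstream_bp: int = 5000
    downstream_bp: int = 1000

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ParseError("promoter extents must be >= 0")


@dataclass
class InteractionRecord:
    """A curated directed edge with its supporting evidence sources."""

    source: str
    target: str
    kind: str  # "tf_mirna" | "mti"
    evidence: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in ("tf_mirna", "mti"):
            raise ParseError(f"unknown edge kind {self.kind!r}")
        if self.source == self.target:
            raise ParseError(f"self-edge not allowed: {self.source}")
        if not self.evidence:
            raise ParseError(
                f"interaction {self.source}->{self.target} has empty evidence"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.kind)


def parse_locus_string(s: str, name: str = "locus") -> MirnaLocus:
    """Parse a ``chrom:start-end:strand`` string into a :class:`MirnaLocus`.

    Whitespace around tokens is tolerated (printed tables often contain a
    stray space after the colon).  Coordinates are 1-based closed.
    """
    m = _LOCUS_RE.match(s)
    if m is None:
        raise ParseError(f"malformed locus string: {s!r}")
    return MirnaLocus(
        name=name,
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=m.group("strand"),
    )


def promoter_window(locus: MirnaLocus, cfg: PromoterConfig | None = None) -> tuple[str, int, int]:
    """Strand-aware promoter interval around the locus 5' end, clipped at 1.

    Plus strand: ``[start - upstream, start + downstream]``; minus strand:
    ``[end - downstream, end + upstream]``.  Returned as
    ``(chrom, lo, hi)`` in 1-based closed coordinates.
    """
    cfg = cfg or PromoterConfig()
    anchor = locus.five_prime
    if locus.strand == "+":
        lo, hi = anchor - cfg.upstream_bp, anchor + cfg.downstream_bp
    else:
        lo, hi = anchor - cfg.downstream_bp, anchor + cfg.upstream_bp
    return (locus.chrom, max(1, lo), max(1, hi))


@dataclass(frozen=True)
class BedPeak:
    """A ChIP-Seq peak; stored 1-based closed after conversion from BED."""

    tf: str
    chrom: str
    start: int
    end: int
    score: float | None = None


def read_peaks_bed(path: str | Path, tf: str | None = None) -> list[BedPeak]:
    """Read a BED file of peaks; the name column (4th) carries the TF unless
    ``tf`` overrides it.  BED is 0-based half-open and converted here."""
    peaks: list[BedPeak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED record has <3 fields")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        name = tf if tf is not None else (fields[3] if len(fields) > 3 else "peak")
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        peaks.append(BedPeak(tf=name, chrom=chrom, start=start0 + 1, end=end0, score=score))
    return peaks


def _check_chrom_namespace(peaks: Sequence[BedPeak], loci: Sequence[MirnaLocus]) -> None:
    if not peaks or not loci:
        return
    peak_chroms = {p.chrom for p in peaks}
    loci_chroms = {l.chrom for l in loci}
    if peak_chroms & loci_chroms:
        return
    peak_pref = any(c.startswith("chr") for c in peak_chroms)
    loci_pref = any(c.startswith("chr") for c in loci_chroms)
    if peak_pref != loci_pref:
        raise ParseError(
            "peak and locus chromosome names do not overlap and differ in 'chr' "
            "prefix usage (e.g. 'chr12' vs '12'); harmonise naming before overlap"
        )


def infer_tf_mirna_from_peaks(
    peaks: Sequence[BedPeak],
    loci: Sequence[MirnaLocus],
    cfg: PromoterConfig | None = None,
    min_score: float | None = None,
) -> list[InteractionRecord]:
    """Emit a TF->miRNA edge for every (TF, miRNA) pair where at least one
    peak overlaps the miRNA promoter window by >= 1 bp.

    Duplicate (TF, miRNA) hits collapse to a single record with evidence
    ``{"chip"}``.  ``min_score`` optionally drops peaks below a score cutoff.
    """
    cfg = cfg or PromoterConfig()
    _check_chrom_namespace(peaks, loci)
    seen: dict[tuple[str, str], InteractionRecord] = {}
    windows = [(l, promoter_window(l, cfg)) for l in loci]
    for peak in peaks:
        if min_score is not None and (peak.score is None or peak.score < min_score):
            continue
        for locus, (chrom, lo, hi) in windows:
            if peak.chrom != chrom:
                continue
            if peak.start <= hi and peak.end >= lo:  # closed-interval overlap
                key = (peak.tf, locus.name)
                if key not in seen:
                    seen[key] = InteractionRecord(
                        source=peak.tf, target=locus.name,
                        kind="tf_mirna", evidence={"chip"},
                    )
    return list(seen.values())


def merge_sources(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Union interaction records: unique by (source, target, kind), evidence
    sets merged.  Idempotent and order-independent."""
    merged: dict[tuple[str, str, str], InteractionRecord] = {}
    for rec in records:
        if rec.key in merged:
            merged[rec.key].evidence |= rec.evidence
        else:
            merged[rec.key] = InteractionRecord(
                source=rec.source, target=rec.target,
                kind=rec.kind, evidence=set(rec.evidence),
            )
    return sorted(merged.values(), key=lambda r: r.key)


def summarize_interactions(records: Sequence[InteractionRecord]) -> dict:
    """Unique node / pair counts per edge kind, for reporting."""
    tf_edges = [r for r in records if r.kind == "tf_mirna"]
    mti_edges = [r for r in records if r.kind == "mti"]
    return {
        "n_tf_mirna_pairs": len(tf_edges),
        "n_tfs": len({r.source for r in tf_edges}),
        "n_mirnas_regulated": len({r.target for r in tf_edges}),
        "n_mti_pairs": len(mti_edges),
        "n_mirnas_with_targets": len({r.source for r in mti_edges}),
        "n_target_genes": len({r.target for r in mti_edges}),
    }


def strip_species_prefix(name: str) -> str:
    """Drop a leading species prefix such as ``mmu-`` or ``hsa-``."""
    return _SPECIES_PREFIX_RE.sub("", name)


def normalize_mirna_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a miRNA name to its canonical form via an alias table.

    The species prefix is stripped and lookup is case-insensitive on the
    stripped name.  Unmapped names pass through (stripped) with an
    :class:`UnmappedNameWarning`.  Idempotent: canonical names map to
    themselves.
    """
    stripped = strip_species_prefix(name.strip())
    if aliases:
        lowered = {strip_species_prefix(k).lower(): v for k, v in aliases.items()}
        canon = lowered.get(stripped.lower())
        if canon is not None:
            return canon
        if stripped in set(aliases.values()):
            return stripped
        warnings.warn(f"miRNA name {name!r} not in alias table", UnmappedNameWarning)
    return stripped


def read_tf_mirna_tsv(path: str | Path, evidence: str | None = None) -> list[InteractionRecord]:
    """Read a TransmiR-style TSV with columns (tf, mirna, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("tf", "mirna"), path)
    records = []
    for row in df.itertuples(index=False):
        src = evidence or getattr(row, "source", None) or "curated"
        records.append(InteractionRecord(row.tf, row.mirna, "tf_mirna", {src}))
    return records


def read_mti_tsv(path: str | Path) -> list[InteractionRecord]:
    """Read a miRTarBase-style TSV with columns (mirna, gene, source[, evidence])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("mirna", "gene"), path)
    records = []
    for row in df.itertuples(index=False):
        src = getattr(row, "source", None) or "curated"
        records.append(InteractionRecord(row.mirna, str(row.gene).upper(), "mti", {src}))
    return records


def write_interactions_tsv(records: Sequence[InteractionRecord], path: str | Path) -> None:
    rows = [
        {"source": r.source, "target": r.target, "kind": r.kind,
         "evidence": ",".join(sorted(r.evidence))}
        for r in records
    ]
    pd.DataFrame(rows, columns=["source", "target", "kind", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_loci_gff3(path: str | Path) -> list[MirnaLocus]:
    """Read miRNA loci from a miRBase-style GFF3 (Name attribute, 1-based)."""
    loci = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: GFF3 record has {len(fields)} fields")
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("ID")
        if not name:
            raise ParseError(f"{path}:{lineno}: GFF3 record lacks Name/ID attribute")
        loci.append(
            MirnaLocus(name=name, chrom=fields[0], start=int(fields[3]),
                       end=int(fields[4]), strand=fields[6])
        )
    return loci


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
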