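"""Reference database curation for the LSU (28S) LROR–FLR2 amplicon region.

Reference sequences for Glomeromycota and outgroup taxa were historically
amplified with many different primer combinations, so raw database entries
start and end at different positions of the LSU. This module standardises
them: each sequence is trimmed in silico to the region between the pipeline
primers (LROR forward, FLR2 reverse), short entries that never reached the
primer sites are padded with N to the common region length, and every record
carries its family (or outgroup group) label. The same primer machinery
clips primers off study reads, and the curated region can be cut down to the
study read lengths (first r1 bp, last r2 bp reverse-complemented) so that
references and Illumina reads cover exactly the same sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .iupac import SequenceError, encode_mask, revcomp, validate_iupac

# Default pipeline primers (LROR forward / FLR2 reverse). These strings are
# the published primer sequences from the primer literature (Vilgalys lab
# LROR; Trouvelot/FLR series FLR2); they are configuration, not constants —
# override them via PrimerPair/config for other marker systems.
DEFAULT_LROR = "ACCCGCTGAACTTAAGC"
DEFAULT_FLR2 = "GTCGTTTAAAGCCATTACGTC"


class PrimerError(ValueError):
    """Raised for malformed primer definitions or malformed references."""


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate forward/reverse primer pair with a mismatch tolerance."""

    forward_name: str = "LROR"
    forward_seq: str = DEFAULT_LROR
    reverse_name: str = "FLR2"
    reverse_seq: str = DEFAULT_FLR2
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not self.forward_seq or not self.reverse_seq:
            raise PrimerError("primer sequences must be non-empty")
        validate_iupac(self.forward_seq, context=f"primer {self.forward_name}")
        validate_iupac(self.reverse_seq, context=f"primer {self.reverse_name}")
        if not 0.0 <= self.max_error_rate < 0.5:
            raise PrimerError("max_error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class PrimerMatch:
    start: int
    end: int  # half-open
    mismatches: int


def find_primer_site(seq: str, primer: str, max_error_rate: float) -> PrimerMatch | None:
    """Locate the best (fewest-mismatch, leftmost) window matching a primer.

    IUPAC codes match every base they denote; N on either side counts as a
    match. Indels are not modelled — windows have exactly the primer length.
    Returns None when no window has <= floor(max_error_rate * |primer|)
    mismatches.
    """
    if not seq:
        raise SequenceError("empty sequence")
    seq_mask = encode_mask(seq)
    primer_mask = encode_mask(primer)
    k = len(primer)
    if len(seq) < k:
        return None
    n_windows = len(seq) - k + 1
    mism = np.zeros(n_windows, dtype=np.int32)
    for j in range(k):
        mism += (seq_mask[j:j + n_windows] & primer_mask[j]) == 0
    allowed = int(max_error_rate * k)
    best = int(mism.min())
    if best > allowed:
        return None
    start = int(np.argmin(mism))  # argmin is leftmost on ties
    return PrimerMatch(start=start, end=start + k, mismatches=best)


@dataclass(frozen=True)
class TrimResult:
    region: str
    trimmed: bool
    orientation: str  # "forward" | "reverse" | "unknown"
    forward_site: PrimerMatch | None = None
    reverse_site: PrimerMatch | None = None


def trim_reference(raw_seq: str, primers: PrimerPair,
                   max_error_rate: float | None = None) -> TrimResult:
    """Extract the inter-primer region from a raw reference sequence.

    Both strand orientations are tried; the orientation in which both primer
    sites are found (fewest total mismatches on ties) wins and the region is
    returned in forward (LROR -> FLR2) orientation, primers excluded. If only
    one or neither primer is found the full sequence is returned flagged
    untrimmed, to be padded downstream.
    """
    if not raw_seq:
        raise SequenceError("empty reference sequence")
    rate = primers.max_error_rate if max_error_rate is None else max_error_rate
    rc_rev = revcomp(primers.reverse_seq)

    candidates = []
    for orientation, seq in (("forward", raw_seq.upper()), ("reverse", revcomp(raw_seq.upper()))):
        fwd = find_primer_site(seq, primers.forward_seq, rate)
        rev = find_primer_site(seq, rc_rev, rate)
        candidates.append((orientation, seq, fwd, rev))

    both = [c for c in candidates if c[2] is not None and c[3] is not None]
    if both:
        orientation, seq, fwd, rev = min(
            both, key=lambda c: c[2].mismatches + c[3].mismatches)
        if rev.start < fwd.end:
            raise PrimerError(
                f"reverse primer site [{rev.start},{rev.end}) upstream of forward "
                f"site [{fwd.start},{fwd.end}): malformed reference")
        return TrimResult(region=seq[fwd.end:rev.start], trimmed=True,
                          orientation=orientation, forward_site=fwd, reverse_site=rev)
    return TrimResult(region=raw_seq.upper(), trimmed=False, orientation="unknown")


def pad_to_region(seq: str, target_region_length: int, anchor: str = "start") -> tuple[str, int, int]:
    """Pad a (sub-region) sequence to the target length with N.

    anchor="start" keeps the sequence 5'-anchored (N appended); anchor="end"
    keeps it 3'-anchored (N prepended). Returns (padded, pad_left, pad_right).
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    if len(seq) > target_region_length:
        raise ValueError(
            f"sequence length {len(seq)} exceeds target region length "
            f"{target_region_length}; trim before padding")
    n = target_region_length - len(seq)
    if anchor == "start":
        return seq + "N" * n, 0, n
    return "N" * n + seq, n, 0


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    accession: str
    taxon: str
    group_label: str
    raw_seq: str
    region_seq: str
    pad_left: int
    pad_right: int
    trimmed: bool


@dataclass
class ReferenceDB:
    """Primer-anchored reference sequences with family/outgroup labels."""

    records: list[ReferenceRecord]
    target_region_length: int
    primer_pair: PrimerPair
    family_names: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rid: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def region_seqs(self) -> dict[str, str]:
        return {r.id: r.region_seq for r in self.records}

    def summary(self) -> dict:
        return {
            "n_records": len(self.records),
            "n_trimmed": sum(r.trimmed for r in self.records),
            "n_untrimmed": sum(not r.trimmed for r in self.records),
            "n_padded": sum((r.pad_left + r.pad_right) > 0 for r in self.records),
            "target_region_length": self.target_region_length,
            "families": sorted(self.family_names),
        }


def read_family_map(path: str | Path) -> pd.DataFrame:
    """Read the id -> group_label/taxon/accession TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "group_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"family map missing columns: {sorted(missing)}")
    for col in ("taxon", "accession", "is_amf"):
        if col not in df.columns:
            df[col] = ""
    return df


def build_reference_db(
    fasta: str | Path | Iterable[tuple[str, str]],
    family_map: str | Path | pd.DataFrame,
    primers: PrimerPair | None = None,
    target_region_length: int | None = None,
    *,
    anchor: str = "start",
    strict: bool = False,
) -> ReferenceDB:
    """Curate raw reference sequences into a primer-anchored database.

    Every record is trimmed to the inter-primer region (both orientations
    tried) and padded with N to a common target length (default: the longest
    trimmed region). Records whose primers cannot be located are kept
    untrimmed and padded, unless strict=True drops them.
    """
    primers = primers or PrimerPair()
    if isinstance(fasta, (str, Path)):
        seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta), "fasta")]
    else:
        seqs = list(fasta)
    if not seqs:
        raise ValueError("no reference sequences provided")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in reference FASTA: {dupes}")

    fam = family_map if isinstance(family_map, pd.DataFrame) else read_family_map(family_map)
    fam = fam.set_index("id")
    unknown = [i for i in ids if i not in fam.index]
    if unknown:
        raise ValueError(f"reference ids missing from family map: {unknown}")

    trims: dict[str, TrimResult] = {}
    for rid, seq in seqs:
        trims[rid] = trim_reference(seq, primers)
    if strict:
        seqs = [(i, s) for i, s in seqs if trims[i].trimmed]
        if not seqs:
            raise ValueError("strict mode dropped every record (no primer sites found)")

    target = target_region_length or max(len(trims[i].region) for i, _ in seqs)
    too_long = [i for i, _ in seqs if len(trims[i].region) > target]
    if too_long:
        raise ValueError(
            f"trimmed regions exceed target_region_length={target}: {too_long}")

    records = []
    for rid, seq in seqs:
        tr = trims[rid]
        padded, pl, pr = pad_to_region(tr.region, target, anchor=anchor)
        row = fam.loc[rid]
        records.append(ReferenceRecord(
            id=rid, accession=str(row.get("accession", "")),
            taxon=str(row.get("taxon", "")), group_label=str(row["group_label"]),
            raw_seq=seq.upper(), region_seq=padded,
            pad_left=pl, pad_right=pr, trimmed=tr.trimmed))

    amf_col = fam.loc[ids, "is_amf"] if "is_amf" in fam.columns else None
    if amf_col is not None and amf_col.astype(str).str.len().gt(0).any():
        truthy = {"1", "true", "yes", "amf"}
        families = {str(fam.loc[r.id, "group_label"]) for r in records
                    if str(fam.loc[r.id, "is_amf"]).strip().lower() in truthy}
    else:
        # without an explicit flag, every group label is treated as a family
        families = {r.group_label for r in records}
    return ReferenceDB(records=records, target_region_length=target,
                       primer_pair=primers, family_names=frozenset(families))


@dataclass(frozen=True)
class ReadLengthCut:
    """Forward/reverse read lengths applied to both study reads and references."""

    r1_len: int
    r2_len: int

    def __post_init__(self) -> None:
        if self.r1_len <= 0 or self.r2_len <= 0:
            raise ValueError("read lengths must be positive")

    def validate_against(self, target_region_length: int) -> None:
        if self.r1_len + self.r2_len > target_region_length:
            raise ValueError(
                f"r1_len + r2_len = {self.r1_len + self.r2_len} exceeds the "
                f"reference region length {target_region_length}")


def cut_reference_to_read_lengths(db: ReferenceDB, cut: ReadLengthCut) -> dict[str, tuple[str, str]]:
    """Cut each curated region to read-sized fragments.

    Returns id -> (r1_fragment, r2_fragment) where the R1 fragment is the
    first r1_len bases of the region and the R2 fragment is the last r2_len
    bases reverse-complemented (i.e. in Illumina R2 read orientation).
    """
    cut.validate_against(db.target_region_length)
    out = {}
    for rec in db.records:
        region = rec.region_seq
        out[rec.id] = (region[:cut.r1_len], revcomp(region[-cut.r2_len:]))
    return out


@dataclass(frozen=True)
class ReadPair:
    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: Sequence[int] = ()
    r2_qual: Sequence[int] = ()


@dataclass
class TrimmedReads:
    pairs: list[ReadPair]
    n_input: int
    n_trimmed: int
    n_missing_primer: int
    dropped_ids: list[str]


def trim_read_pair(pairs: Iterable[ReadPair], primers: PrimerPair,
                   *, policy: str = "drop") -> TrimmedReads:
    """Clip the forward primer off R1 5' ends and the reverse primer off R2.

    Primers are matched at the very start of each read within the pair's
    mismatch tolerance. Pairs where either primer is undetectable are dropped
    (policy="drop") or kept unclipped (policy="keep"); both are counted.
    """
    if policy not in ("drop", "keep"):
        raise ValueError("policy must be 'drop' or 'keep'")
    rate = primers.max_error_rate

    def clip(seq: str, qual: Sequence[int], primer: str) -> tuple[str, Sequence[int]] | None:
        k = len(primer)
        if len(seq) < k:
            return None
        site = find_primer_site(seq[:k], primer, rate)
        if site is None:
            return None
        return seq[k:], qual[k:] if len(qual) >= k else ()

    out: list[ReadPair] = []
    n_missing = 0
    dropped: list[str] = []
    n_in = 0
    for pair in pairs:
        n_in += 1
        c1 = clip(pair.r1_seq, pair.r1_qual, primers.forward_seq)
        c2 = clip(pair.r2_seq, pair.r2_qual, primers.reverse_seq)
        if c1 is None or c2 is None:
            n_missing += 1
            if policy == "drop":
                dropped.append(pair.id)
                continue
            out.append(pair)
            continue
        out.append(ReadPair(id=pair.id, r1_seq=c1[0], r2_seq=c2[0],
                            r1_qual=c1[1], r2_qual=c2[1]))
    return TrimmedReads(pairs=out, n_input=n_in, n_trimmed=n_in - n_missing,
                        n_missing_primer=n_missing, dropped_ids=dropped)


def write_region_fasta(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in db.records:
            fh.write(f">{rec.id}\n{rec.region_seq}\n")


def write_fragment_fastas(fragments: Mapping[str, tuple[str, str]],
                          r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, (r1, r2) in fragments.items():
            f1.write(f">{rid}\n{r1}\n")
            f2.write(f">{rid}\n{r2}\n")


def write_manifest(db: ReferenceDB, path: str | Path) -> None:
    manifest = {
        "target_region_length": db.target_region_length,
        "primer_pair": {
            "forward_name": db.primer_pair.forward_name,
            "forward_seq": db.primer_pair.forward_seq,
            "reverse_name": db.primer_pair.reverse_name,
            "reverse_seq": db.primer_pair.reverse_seq,
            "max_error_rate": db.primer_pair.max_error_rate,
        },
        "summary": db.summary(),
        "records": [
            {"id": r.id, "group_label": r.group_label, "taxon": r.taxon,
             "accession": r.accession, "pad_left": r.pad_left,
             "pad_right": r.pad_right, "trimmed": r.trimmed}
            for r in db.records
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
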