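"""MAF-dialect ingestion, CDS-space consequence calling, and mutation filters.

Somatic SNVs are consumed in CDS space (transcript id + 1-based CDS position
in files, 0-based internally).  Consequences are called directly against the
transcript model: missense and nonsense changes count as non-synonymous,
synonymous changes as silent, and anything else (stop-codon positions,
reference mismatches, non-SNVs) is discarded, mirroring the treatment of
variant types in exome-wide selection scans.  The quality filters implement
the six printed exclusion criteria (VAF, supporting reads, population allele
frequency, segmental-duplication score, simple repeats, allele-balance bias)
plus the diploid-region and gene-level (Na/Ns ratio, zero-mutation,
blocklist) filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .errors import (
    DialectError,
    MissingSpectrum,
    OutOfBounds,
    ReferenceMismatch,
)
from .reference import SSB7_LABELS, Transcriptome, TranscriptModel, UNKNOWN

logger = logging.getLogger(__name__)

CONSEQUENCES = ("synonymous", "missense", "nonsense", "other")
NON_SILENT = ("missense", "nonsense")

#: canonical internal column names
CORE_COLUMNS = ("sample", "transcript", "cds_pos", "ref", "alt")
ANNOTATION_COLUMNS = ("vaf", "alt_reads", "pop_af", "segdup", "in_repeat",
                      "abb", "segment_mean")


@dataclass(frozen=True)
class MafDialect:
    """Column-name mapping for a MAF-style tab-separated mutation table.

    Defaults follow TCGA MAF conventions, with positions interpreted as
    1-based CDS coordinates on the named transcript.
    """

    transcript: str = "Transcript_ID"
    position: str = "Start_position"
    ref: str = "Reference_Allele"
    alt: str = "Tumor_Seq_Allele2"
    sample: str = "Tumor_Sample_Barcode"
    #: optional annotation columns, internal name -> file column
    annotations: Mapping[str, str] = field(default_factory=lambda: {
        "vaf": "VAF", "alt_reads": "t_alt_count", "pop_af": "EVS_AF",
        "segdup": "SegDup_Score", "in_repeat": "Simple_Repeat",
        "abb": "ABB_Score", "segment_mean": "Segment_Mean",
    })


DEFAULT_DIALECT = MafDialect()

#: the six printed quality cut-offs; a record is dropped when it violates one
DEFAULT_THRESHOLDS = {
    "vaf_min": 0.1,        # (1) VAF < 0.1
    "alt_reads_min": 5,    # (2) alt-supporting reads < 5
    "pop_af_max": 0.01,    # (3) population (EVS) frequency >= 1%
    "segdup_max": 0.5,     # (4) segmental-duplication score > 0.5
                           # (5) overlapping a simple repeat
    "abb_min": 0.7,        # (6) allele-balance bias score <= 0.7
}

QUALITY_CRITERIA = ("vaf", "alt_reads", "pop_af", "segdup", "in_repeat", "abb")


@dataclass
class Cohort:
    """A named cohort of annotated somatic SNVs."""

    cohort_id: str
    mutations: pd.DataFrame

    def gene_counts(self, transcriptome: Transcriptome) -> pd.DataFrame:
        return gene_counts(self.mutations, transcriptome)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mutations(path: str | Path,
                   dialect: MafDialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a MAF-dialect TSV into the canonical mutation frame.

    Rows whose ref or alt allele is not a single A/C/G/T base (indels, MNVs,
    ``-`` markers) are dropped with a logged count.  Returns columns
    ``sample, transcript, cds_pos (0-based), ref, alt`` plus any optional
    annotation columns found in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {
        "sample": dialect.sample, "transcript": dialect.transcript,
        "cds_pos": dialect.position, "ref": dialect.ref, "alt": dialect.alt,
    }
    missing = [col for col in required.values() if col not in df.columns]
    if missing:
        raise DialectError(f"missing required column(s): {missing}")
    out = pd.DataFrame({name: df[col] for name, col in required.items()})
    for internal, col in dialect.annotations.items():
        if col in df.columns:
            out[internal] = pd.to_numeric(df[col], errors="coerce")
    n0 = len(out)
    snv = (out["ref"].str.fullmatch("[ACGT]").fillna(False)
           & out["alt"].str.fullmatch("[ACGT]").fillna(False)
           & (out["ref"] != out["alt"]))
    pos = pd.to_numeric(out["cds_pos"], errors="coerce")
    snv &= pos.notna()
    dropped = int(n0 - snv.sum())
    if dropped:
        logger.info("read_mutations: dropped %d non-SNV/unparseable rows", dropped)
    out = out[snv].copy()
    out["cds_pos"] = pos[snv].astype(np.int64) - 1  # 1-based file -> 0-based
    return out.reset_index(drop=True)


def write_maf(df: pd.DataFrame, path: str | Path,
              dialect: MafDialect = DEFAULT_DIALECT,
              header_comments: list[str] | None = None) -> None:
    """Write the canonical mutation frame as a MAF-dialect TSV (1-based)."""
    out = pd.DataFrame({
        dialect.sample: df["sample"],
        dialect.transcript: df["transcript"],
        dialect.position: df["cds_pos"].astype(np.int64) + 1,
        dialect.ref: df["ref"],
        dialect.alt: df["alt"],
    })
    for internal, col in dialect.annotations.items():
        if internal in df.columns:
            out[col] = df[internal]
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consequence annotation
# ---------------------------------------------------------------------------

def annotate_consequence(m: Mapping, tx: TranscriptModel) -> dict:
    """Annotate a single mutation record (dict-like) against its transcript.

    Fills ``consequence``, ``class7`` and, when both flanks are known,
    ``class192``.  Raises :class:`OutOfBounds` for positions beyond the CDS
    and :class:`ReferenceMismatch` when the stated reference allele disagrees
    with the CDS.  Positions inside the terminal stop codon are annotated
    ``other`` (discarded downstream, as for any non-missense/nonsense/
    synonymous variant type).
    """
    pos = int(m["cds_pos"])
    if not 0 <= pos < len(tx.cds):
        raise OutOfBounds(
            f"{tx.transcript_id}: CDS position {pos} outside [0, {len(tx.cds)})"
        )
    if tx.cds[pos] != m["ref"]:
        raise ReferenceMismatch(
            f"{tx.transcript_id}:{pos} CDS has {tx.cds[pos]}, record says {m['ref']}"
        )
    out = dict(m)
    five = tx.cds[pos - 1] if pos > 0 else None
    three = tx.cds[pos + 1] if pos + 1 < len(tx.cds) else None
    out["class7"] = reference.classify_substitution7(m["ref"], m["alt"], five, three)
    if five is not None and three is not None:
        out["class192"] = reference.classify_substitution192(
            m["ref"], m["alt"], five, three)
    else:
        out["class192"] = None
    if pos >= tx.counted_length:  # terminal stop codon
        out["consequence"] = "other"
        return out
    ci = pos // 3
    codon = tx.cds[3 * ci:3 * ci + 3]
    alt_codon = codon[:pos % 3] + m["alt"] + codon[pos % 3 + 1:]
    from Bio.Seq import Seq
    ref_aa, alt_aa = str(Seq(codon).translate()), str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        out["consequence"] = "synonymous"
    elif alt_aa == "*":
        out["consequence"] = "nonsense"
    else:
        out["consequence"] = "missense"
    return out


def annotate_mutations(df: pd.DataFrame, transcriptome: Transcriptome,
                       drop_other: bool = True) -> pd.DataFrame:
    """Vectorized consequence and class annotation for a mutation frame.

    Rows on unknown transcripts, out-of-CDS positions, or with a reference
    allele disagreeing with the CDS are flagged and dropped with logged
    counts (the drop reasons appear in the log, not as exceptions, so one
    corrupt row cannot abort a cohort).  ``drop_other`` also removes rows
    annotated ``other`` (terminal-stop positions).
    """
    if df.empty:
        out = df.copy()
        out["consequence"] = pd.Series(dtype=str)
        out["class7"] = pd.Series(dtype="Int64")
        out["class192"] = pd.Series(dtype="Int64")
        return out
    arr = transcriptome._ensure_arrays()
    known = df["transcript"].map(transcriptome._index).notna()
    if (~known).any():
        logger.warning("annotate: %d rows on unknown transcripts dropped",
                       int((~known).sum()))
    df = df[known]
    tx_idx = df["transcript"].map(transcriptome._index).to_numpy(dtype=np.int64)
    pos = df["cds_pos"].to_numpy(dtype=np.int64)

    full_len = np.array([len(t.cds) for t in arr["tx_list"]], dtype=np.int64)
    counted = arr["counted"]
    in_cds = (pos >= 0) & (pos < full_len[tx_idx])
    if (~in_cds).any():
        logger.warning("annotate: %d rows out of CDS bounds dropped",
                       int((~in_cds).sum()))
    df, tx_idx, pos = df[in_cds], tx_idx[in_cds], pos[in_cds]
    in_counted = pos < counted[tx_idx]

    # terminal-stop rows are annotated 'other'; handle counted rows vectorized
    gpos = arr["offsets"][tx_idx] + pos
    gpos_c = gpos[in_counted]
    ref_code = np.array([reference._BASE_CODE[b] for b in df["ref"]],
                        dtype=np.int8)
    alt_code = np.array([reference._BASE_CODE[b] for b in df["alt"]],
                        dtype=np.int8)
    ref_ok = np.ones(len(df), dtype=bool)
    ref_ok[in_counted] = arr["ref"][gpos_c] == ref_code[in_counted]
    # stop-codon rows: check against the raw CDS
    for i in np.flatnonzero(~in_counted):
        tx = arr["tx_list"][tx_idx[i]]
        ref_ok[i] = tx.cds[pos[i]] == df["ref"].iloc[i]
    if (~ref_ok).any():
        logger.warning("annotate: %d rows with reference mismatch dropped",
                       int((~ref_ok).sum()))
    df = df[ref_ok]
    tx_idx, pos, ref_code, alt_code = (tx_idx[ref_ok], pos[ref_ok],
                                       ref_code[ref_ok], alt_code[ref_ok])
    in_counted = pos < counted[tx_idx]
    gpos = arr["offsets"][tx_idx] + pos

    out = df.copy()
    consequence = np.full(len(df), "other", dtype=object)
    class7 = np.full(len(df), -1, dtype=np.int16)
    class192 = np.full(len(df), -1, dtype=np.int16)

    gc = gpos[in_counted]
    a = alt_code[in_counted]
    r = arr["ref"][gc]
    offset = (a.astype(np.int16) - r) % 4  # 1..3 -> event row offset-1
    row = offset - 1
    syn = arr["syn"][row, gc]
    c7 = arr["cls7"][row, gc]
    c192 = arr["cls192"][row, gc]
    pow_ = np.array([16, 4, 1], dtype=np.int16)
    new_codon = arr["codon"][gc] + (a.astype(np.int16) - r) * pow_[arr["frame"][gc]]
    alt_aa_stop = np.isin(new_codon, list(reference._STOP_CODON_IDX))
    cons_counted = np.where(syn, "synonymous",
                            np.where(alt_aa_stop, "nonsense", "missense"))
    consequence[in_counted] = cons_counted
    class7[in_counted] = c7
    class192[in_counted] = c192
    # stop-codon rows keep consequence 'other' but still get a class7 call
    for i in np.flatnonzero(~in_counted):
        tx = arr["tx_list"][tx_idx[i]]
        p = int(pos[i])
        five = tx.cds[p - 1] if p > 0 else None
        three = tx.cds[p + 1] if p + 1 < len(tx.cds) else None
        lab = reference.classify_substitution7(
            df["ref"].iloc[i], df["alt"].iloc[i], five, three)
        class7[i] = SSB7_LABELS.index(lab)

    out["consequence"] = consequence
    out["class7"] = class7
    out["class192"] = class192
    if drop_other:
        n_other = int((out["consequence"] == "other").sum())
        if n_other:
            logger.info("annotate: %d 'other' consequence rows dropped", n_other)
        out = out[out["consequence"] != "other"]
    return out.reset_index(drop=True)


def gene_counts(df: pd.DataFrame, transcriptome: Transcriptome) -> pd.DataFrame:
    """Per-gene non-silent (n) and silent (s) mutation tallies."""
    gene = df["transcript"].map(transcriptome.gene_of)
    tab = pd.DataFrame({
        "gene": gene,
        "non_silent": df["consequence"].isin(NON_SILENT).astype(int),
        "silent": (df["consequence"] == "synonymous").astype(int),
    })
    out = tab.groupby("gene", sort=True).sum()
    out.columns = ["n", "s"]
    return out


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

def apply_quality_filters(df: pd.DataFrame,
                          thresholds: Mapping[str, float] | None = None
                          ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the six per-mutation quality criteria.

    A record is dropped iff it violates at least one criterion; records
    lacking an annotation column pass that criterion (logged once).  The drop
    ledger attributes each dropped record to the first criterion it violates,
    in the documented order vaf, alt_reads, pop_af, segdup, in_repeat, abb,
    so input count == retained + sum(ledger).
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})

    def col(name):
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce")
        logger.warning("quality filter: column %r absent; criterion passes", name)
        return pd.Series(np.nan, index=df.index)

    violations = {
        "vaf": col("vaf") < th["vaf_min"],                  # strict <
        "alt_reads": col("alt_reads") < th["alt_reads_min"],
        "pop_af": col("pop_af") >= th["pop_af_max"],        # inclusive >=
        "segdup": col("segdup") > th["segdup_max"],         # strict >
        "in_repeat": col("in_repeat").fillna(0) > 0,
        "abb": col("abb") <= th["abb_min"],                 # inclusive <=
    }
    # NaN comparisons are False: missing annotations pass by design
    ledger: dict[str, int] = {}
    already = pd.Series(False, index=df.index)
    for crit in QUALITY_CRITERIA:
        v = violations[crit].fillna(False) & ~already
        ledger[crit] = int(v.sum())
        already |= v
    retained = df[~already].reset_index(drop=True)
    logger.info("quality filters: %d/%d retained (%s)", len(retained), len(df),
                ledger)
    return retained, ledger


def filter_diploid(df: pd.DataFrame,
                   segment_means: pd.DataFrame | None = None,
                   low: float = -0.01, high: float = 0.01) -> pd.DataFrame:
    """Retain mutations in copy-number-diploid regions.

    A record is kept when its copy-number ``segment_mean`` lies in
    ``[low, high]`` (inclusive; defaults to the diploid band [-0.01, 0.01]).
    ``segment_means`` may supply the values as a (sample, transcript,
    segment_mean) table joined on sample and transcript; otherwise the
    frame's own ``segment_mean`` column is used.  Records with no segment
    information are dropped with a warning.
    """
    if segment_means is not None:
        sm = segment_means.rename(columns={segment_means.columns[-1]:
                                           "segment_mean"})
        df = df.drop(columns=["segment_mean"], errors="ignore").merge(
            sm, on=["sample", "transcript"], how="left")
    if "segment_mean" not in df.columns:
        logger.warning("filter_diploid: no segment means at all; 0 retained")
        return df.iloc[0:0]
    vals = pd.to_numeric(df["segment_mean"], errors="coerce")
    missing = int(vals.isna().sum())
    if missing:
        logger.warning("filter_diploid: %d records without segment info dropped",
                       missing)
    keep = (vals >= low) & (vals <= high)
    return df[keep.fillna(False)].reset_index(drop=True)


def apply_gene_filters(df: pd.DataFrame, transcriptome: Transcriptome,
                       spectra: Mapping[str, "reference.SiteSpectrum"],
                       blocklist: set[str] | None = None,
                       max_na_ns_ratio: float = 5.0
                       ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Remove genes failing the gene-level criteria.

    Drops blocklisted genes (known exome false positives / non-expressed
    lists supplied externally), genes whose uncorrected Na/Ns site ratio
    exceeds ``max_na_ns_ratio``, and genes with zero silent and zero
    non-silent mutations.  Returns the filtered frame and the per-reason
    removed-gene lists.
    """
    blocklist = blocklist or set()
    counts = gene_counts(df, transcriptome)
    removed = {"blocklist": [], "na_ns_ratio": [], "no_mutations": []}
    drop: set[str] = set()
    for gene in counts.index:
        if gene not in spectra:
            raise MissingSpectrum(f"no site spectrum for gene {gene}")
        if gene in blocklist:
            removed["blocklist"].append(gene)
            drop.add(gene)
            continue
        spec = spectra[gene]
        if spec.total_ns > 0 and spec.total_na / spec.total_ns > max_na_ns_ratio:
            removed["na_ns_ratio"].append(gene)
            drop.add(gene)
        elif spec.total_ns == 0:
            removed["na_ns_ratio"].append(gene)
            drop.add(gene)
    zero = counts[(counts["n"] == 0) & (counts["s"] == 0)].index
    removed["no_mutations"] = [g for g in zero if g not in drop]
    drop |= set(zero)
    gene = df["transcript"].map(transcriptome.gene_of)
    out = df[~gene.isin(drop)].reset_index(drop=True)
    if drop:
        logger.info("gene filters removed %d genes (%s retained mutations)",
                    len(drop), len(out))
    return out, removed
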