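"""Immunopeptidome region analysis.

Epitope intervals (amino-acid coordinates on proteins) are fused into one
super-epitope mask and the remaining parts of the same proteins into one
super-non-epitope mask; proteins without any annotated epitope contribute to
neither.  dN/dS over a mask is computed with the cohort-level SSB correction
weights (not re-estimated from the region's own mutations), so a region's
ratio is directly comparable to the exome-wide value.

Significance of epitope-specific constraint comes from a coordinate-shifting
permutation test: each epitope interval is re-placed, keeping its length and
protein, uniformly among start positions fully contained in the protein's
non-epitope territory (the first two amino acids of every protein are
excluded as placement territory), the mask dN/dS is recomputed per
permutation, and the one-sided exact p-value is
(1 + #{null <= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import mutations as mut
from . import selection
from .errors import Degenerate, EmptyRegion, OutOfBounds, UnknownProtein
from .reference import (
    N_CLASSES,
    SiteSpectrum,
    Transcriptome,
    count_sites_by_gene,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Region sets
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a 3-column BED-like TSV of (protein_id, aa_start, aa_end),
    1-based closed intervals."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "aa_start", "aa_end"],
                     dtype={"protein_id": str})
    df["aa_start"] = df["aa_start"].astype(int)
    df["aa_end"] = df["aa_end"].astype(int)
    if (df["aa_start"] < 1).any() or (df["aa_start"] > df["aa_end"]).any():
        raise OutOfBounds("region with aa_start < 1 or aa_start > aa_end")
    return df


@dataclass
class SuperRegion:
    """A fused nucleotide-level mask across proteins with its site totals.

    ``aa_masks`` maps protein (transcript) id to a boolean array over the
    protein's amino acids; ``spectrum`` holds the per-class Na/Ns site totals
    restricted to the masked codons.
    """

    system: str
    aa_masks: dict[str, np.ndarray] = field(default_factory=dict)
    spectrum: SiteSpectrum | None = None

    @property
    def n_aa(self) -> int:
        return int(sum(m.sum() for m in self.aa_masks.values()))


class _RegionIndex:
    """Per-amino-acid site and mutation-count tables for the proteins that
    carry regions, enabling fast mask aggregation during permutations."""

    def __init__(self, transcriptome: Transcriptome, proteins: list[str],
                 system: str = "SSB7"):
        arr = transcriptome._ensure_arrays()
        k = N_CLASSES[system]
        cls = arr["cls7"] if system == "SSB7" else arr["cls192"]
        self.system = system
        self.proteins = proteins
        self.protein_len: dict[str, int] = {}
        self.aa_offset: dict[str, int] = {}
        na_rows, ns_rows = [], []
        off = 0
        for pid in proteins:
            if pid not in transcriptome:
                raise UnknownProtein(f"unknown protein/transcript {pid}")
            i = transcriptome.index_of(pid)
            lo, hi = int(arr["offsets"][i]), int(arr["offsets"][i + 1])
            lc = hi - lo
            n_aa = lc // 3
            self.protein_len[pid] = n_aa
            self.aa_offset[pid] = off
            off += n_aa
            na = np.zeros((lc, k)); ns = np.zeros((lc, k))
            for row in range(3):
                c = cls[row, lo:hi].astype(np.int64)
                keep = c >= 0
                syn = arr["syn"][row, lo:hi]
                pos = np.arange(lc)
                np.add.at(na, (pos[keep & ~syn], c[keep & ~syn]), 1 / 3)
                np.add.at(ns, (pos[keep & syn], c[keep & syn]), 1 / 3)
            na_rows.append(na.reshape(n_aa, 3, k).sum(axis=1))
            ns_rows.append(ns.reshape(n_aa, 3, k).sum(axis=1))
        self.total_aa = off
        self.na_aa = np.vstack(na_rows) if na_rows else np.zeros((0, k))
        self.ns_aa = np.vstack(ns_rows) if ns_rows else np.zeros((0, k))
        self.n_aa_counts = np.zeros(off)
        self.s_aa_counts = np.zeros(off)

    def add_mutations(self, df: pd.DataFrame, transcriptome: Transcriptome):
        sub = df[df["transcript"].isin(self.aa_offset)]
        for pid, g in sub.groupby("transcript"):
            aa = g["cds_pos"].to_numpy() // 3
            valid = aa < self.protein_len[pid]
            aa = aa[valid]
            cons = g["consequence"].to_numpy()[valid]
            idx = self.aa_offset[pid] + aa
            nonsil = np.isin(cons, mut.NON_SILENT)
            np.add.at(self.n_aa_counts, idx[nonsil], 1)
            np.add.at(self.s_aa_counts, idx[cons == "synonymous"], 1)

    def global_aa(self, pid: str, aa_mask: np.ndarray) -> np.ndarray:
        return self.aa_offset[pid] + np.flatnonzero(aa_mask)

    def mask_stats(self, aa_idx: np.ndarray, w: np.ndarray
                   ) -> tuple[int, int, float, float]:
        na = self.na_aa[aa_idx].sum(axis=0)
        ns = self.ns_aa[aa_idx].sum(axis=0)
        return (int(self.n_aa_counts[aa_idx].sum()),
                int(self.s_aa_counts[aa_idx].sum()),
                float(w @ na), float(w @ ns))


def _merge_intervals(df: pd.DataFrame, protein_len: Mapping[str, int]
                     ) -> dict[str, np.ndarray]:
    """1-based closed intervals -> per-protein boolean amino-acid masks."""
    masks: dict[str, np.ndarray] = {}
    for pid, g in df.groupby("protein_id"):
        if pid not in protein_len:
            raise UnknownProtein(f"unknown protein/transcript {pid}")
        n_aa = protein_len[pid]
        m = np.zeros(n_aa, dtype=bool)
        for _, r in g.iterrows():
            if r["aa_end"] > n_aa:
                raise OutOfBounds(
                    f"{pid}: interval [{r['aa_start']},{r['aa_end']}] beyond "
                    f"protein length {n_aa}")
            m[r["aa_start"] - 1:r["aa_end"]] = True
        masks[str(pid)] = m
    return masks


def build_super_regions(regions: pd.DataFrame, transcriptome: Transcriptome,
                        system: str = "SSB7"
                        ) -> tuple[SuperRegion, SuperRegion]:
    """Fuse epitope intervals into the super-epitope and super-non-epitope.

    Overlapping intervals are merged per protein; the complement is taken
    within proteins that carry at least one epitope.  Both masks return their
    per-class site spectra restricted to the masked codons.
    """
    proteins = sorted(regions["protein_id"].unique())
    index = _RegionIndex(transcriptome, proteins, system)
    epi_masks = _merge_intervals(regions, index.protein_len)
    non_masks = {pid: ~m for pid, m in epi_masks.items() if (~m).any()}

    def spectrum_of(masks: dict[str, np.ndarray]) -> SiteSpectrum:
        k = N_CLASSES[system]
        na = np.zeros(k); ns = np.zeros(k)
        for pid, m in masks.items():
            idx = index.global_aa(pid, m)
            na += index.na_aa[idx].sum(axis=0)
            ns += index.ns_aa[idx].sum(axis=0)
        return SiteSpectrum(system, na, ns)

    epi = SuperRegion(system, epi_masks, spectrum_of(epi_masks))
    non = SuperRegion(system, non_masks, spectrum_of(non_masks))
    return epi, non


# ---------------------------------------------------------------------------
# Region dN/dS
# ---------------------------------------------------------------------------

def region_dnds(region: SuperRegion, df: pd.DataFrame,
                transcriptome: Transcriptome,
                weights: np.ndarray) -> dict:
    """dN/dS over a fused mask using cohort-level correction weights."""
    if region.n_aa == 0:
        raise EmptyRegion("mask covers no position")
    index = _RegionIndex(transcriptome, sorted(region.aa_masks), region.system)
    index.add_mutations(df, transcriptome)
    aa_idx = np.concatenate([index.global_aa(pid, m)
                             for pid, m in region.aa_masks.items()])
    n, s, na_c, ns_c = index.mask_stats(aa_idx, weights)
    if n + s == 0:
        return {"n": 0, "s": 0, "na_corr": na_c, "ns_corr": ns_c,
                "dn": 0.0, "ds": 0.0, "dnds": math.nan,
                "dnds_defined": False, "p": math.nan}
    dn, ds, dnds, defined = selection.gene_dnds(n, s, na_c, ns_c)
    return {"n": n, "s": s, "na_corr": na_c, "ns_corr": ns_c, "dn": dn,
            "ds": ds, "dnds": dnds, "dnds_defined": defined,
            "p": selection.neutrality_test(n, s, na_c, ns_c)}


# ---------------------------------------------------------------------------
# Coordinate-shifting permutation test
# ---------------------------------------------------------------------------

def _eligible_starts(eligible: np.ndarray, length: int,
                     placement: str = "contained") -> np.ndarray:
    """0-based start positions for a length-``length`` window.

    ``"contained"`` requires the window to lie fully inside the eligible
    territory; ``"overlap"`` only requires it to touch at least one eligible
    position (while staying within the first ``eligible.size`` positions).
    """
    if length > eligible.size:
        return np.array([], dtype=np.int64)
    hits = np.convolve(eligible.astype(np.int64),
                       np.ones(length, dtype=np.int64), mode="valid")
    ok = hits == length if placement == "contained" else hits > 0
    return np.flatnonzero(ok)


def permutation_test(regions: pd.DataFrame, transcriptome: Transcriptome,
                     df: pd.DataFrame, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0,
                     system: str = "SSB7",
                     weights: np.ndarray | None = None,
                     placement: str = "contained") -> dict:
    """Coordinate-shifting permutation test for epitope-specific selection.

    Per permutation, every interval keeps its protein and length and is
    re-placed uniformly among starts fully contained in the protein's
    non-epitope territory (``placement="overlap"`` relaxes this to touching
    it), excluding the first two amino acids; intervals with no eligible
    placement are skipped with a warning.  The observed
    dN/dS is computed on the annotated intervals as given.  One-sided
    p = (1 + #{null dnds <= observed}) / (1 + n_perm); permutations with
    s = 0 count as +inf (never below the observed value).

    Returns observed statistics, the p-value, and the null distribution.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    proteins = sorted(regions["protein_id"].unique())
    index = _RegionIndex(transcriptome, proteins, system)
    index.add_mutations(df, transcriptome)
    if weights is None:
        weights = selection.cohort_weights(
            df, count_sites_by_gene(transcriptome, system), system)
    epi_masks = _merge_intervals(regions, index.protein_len)

    # observed statistic on the annotated intervals as given
    obs_idx = np.concatenate([index.global_aa(pid, m)
                              for pid, m in epi_masks.items()])
    n, s, na_c, ns_c = index.mask_stats(obs_idx, weights)
    if s == 0 or na_c <= 0 or ns_c <= 0:
        raise Degenerate("observed epitope mask has no synonymous mutations "
                         "or degenerate sites")
    observed = (n / na_c) / (s / ns_c)

    # eligible placements per interval: non-epitope territory, aa >= 3
    placements: list[tuple[str, int, np.ndarray]] = []
    skipped = 0
    for _, r in regions.iterrows():
        pid = str(r["protein_id"])
        territory = ~epi_masks[pid]
        territory[:2] = False  # first two amino acids excluded
        length = int(r["aa_end"] - r["aa_start"] + 1)
        starts = _eligible_starts(territory, length, placement)
        if starts.size == 0:
            skipped += 1
            continue
        placements.append((pid, length, starts))
    if skipped:
        logger.warning("permutation_test: %d interval(s) without eligible "
                       "placement skipped", skipped)
    if not placements:
        raise Degenerate("no interval has an eligible null placement")

    null = np.empty(n_perm)
    aa_off = np.array([index.aa_offset[pid] for pid, _, _ in placements])
    for b in range(n_perm):
        pieces = []
        for (pid, length, starts), off in zip(placements, aa_off):
            s0 = int(starts[rng.integers(starts.size)])
            pieces.append(off + np.arange(s0, s0 + length))
        aa_idx = np.unique(np.concatenate(pieces))
        nb, sb, nab, nsb = index.mask_stats(aa_idx, weights)
        if sb == 0 or nab <= 0 or nsb <= 0:
            null[b] = math.inf
        else:
            null[b] = (nb / nab) / (sb / nsb)
    p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    return {"observed_dnds": float(observed), "n": n, "s": s, "p": float(p),
            "n_perm": n_perm, "null": null,
            "n_intervals_used": len(placements), "n_intervals_skipped": skipped}
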