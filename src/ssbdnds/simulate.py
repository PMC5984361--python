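"""Neutral and selection-laden somatic mutation simulation and benchmarking.

The generator draws SNVs from a transcriptome under a 7-class substitution
signature: a class is sampled from the signature, then a (position,
alternate) event uniformly among the transcriptome's events of that class, so
gene composition enters through each gene's eligible-site counts — mutation
counts per gene are proportional to sequence content, not fixed per gene.
Selection is injected afterwards per gene: non-synonymous mutations are
thinned with probability omega (omega < 1) or topped up by additional draws
from the gene's own non-synonymous event pool (omega > 1), leaving synonymous
mutations untouched, so the injected omega is the asymptotic dN/dS of the
gene by construction.

The default signature emulates a pan-cancer somatic spectrum dominated by
C>T transitions, with CpG transitions elevated above all other classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mutations as mut
from . import selection
from .errors import ConfigError
from .reference import (
    BASES,
    SSB7_LABELS,
    Transcriptome,
    TranscriptModel,
    count_sites_by_gene,
)

logger = logging.getLogger(__name__)

#: default 7-class signature (pan-cancer-like: C>T and CpG>N dominant)
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "A>T": 0.07, "A>C": 0.08, "A>G": 0.12,
    "C>A": 0.15, "C>T": 0.25, "C>G": 0.08, "CpG>N": 0.25,
}

_STOPS = ("TAA", "TAG", "TGA")
_BASE_ARR = np.array(list(BASES))


@dataclass
class SimulationConfig:
    """Configuration of one simulated cohort.

    ``class_probs`` is the simulated mutational signature over the seven
    SSB7 classes; ``selection_targets`` maps gene id to the injected dN/dS
    omega (absent genes stay neutral); ``n_samples`` defaults to one sample
    per ~150 mutations, the order of magnitude of per-sample exome loads in
    large pan-cancer cohorts.
    """

    n_mutations: int
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    selection_targets: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    n_samples: int | None = None

    def probs_array(self) -> np.ndarray:
        p = np.array([self.class_probs.get(lab, 0.0) for lab in SSB7_LABELS])
        if (p < 0).any() or p.sum() <= 0:
            raise ConfigError("class_probs must be non-negative and sum > 0")
        if abs(p.sum() - 1) > 1e-6:
            raise ConfigError(f"class_probs sum to {p.sum():.6f}, not 1")
        return p / p.sum()


# ---------------------------------------------------------------------------
# Toy transcriptome
# ---------------------------------------------------------------------------

def make_toy_transcriptome(n_genes: int, mean_length: int = 1500,
                           length_sigma: float = 0.55, gc_bias: float = 0.5,
                           seed: int | np.random.Generator = 0,
                           min_length: int = 300, max_length: int = 9999
                           ) -> Transcriptome:
    """Generate a reproducible toy transcriptome of valid coding sequences.

    Coding lengths (start codon included, terminal stop excluded) are drawn
    log-normally with median ``mean_length`` and log-scale ``length_sigma``
    (the defaults give the ~1.5 kb typical of human CDSs), rounded to codons
    and clipped to [min_length, max_length].  Bases are i.i.d. with G+C
    probability ``gc_bias``; internal stop codons are rejected by resampling;
    an ATG start is prepended and a random stop codon appended.
    """
    if n_genes < 0 or not 0 < gc_bias < 1:
        raise ConfigError(f"infeasible n_genes={n_genes} or gc_bias={gc_bias}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if n_genes == 0:
        return Transcriptome([])
    lengths = np.exp(rng.normal(np.log(mean_length), length_sigma, n_genes))
    lengths = np.clip((lengths // 3).astype(int) * 3, min_length, max_length)
    base_p = np.array([(1 - gc_bias) / 2, gc_bias / 2,
                       gc_bias / 2, (1 - gc_bias) / 2])
    stop_idx = {16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1])
                + "ACGT".index(c[2]) for c in _STOPS}

    n_codons = (lengths // 3 - 1).astype(int)  # minus the fixed ATG
    total = int(n_codons.sum())
    codons = rng.choice(4, size=(total, 3), p=base_p)
    idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    bad = np.isin(idx, list(stop_idx))
    while bad.any():  # resample internal stop codons
        codons[bad] = rng.choice(4, size=(int(bad.sum()), 3), p=base_p)
        idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
        bad = np.isin(idx, list(stop_idx))
    flat = _BASE_ARR[codons].reshape(-1)
    offsets = np.concatenate([[0], np.cumsum(n_codons * 3)])
    stops = rng.choice(len(_STOPS), size=n_genes)
    width = len(str(max(n_genes - 1, 1)))
    records = []
    for i in range(n_genes):
        body = "".join(flat[offsets[i]:offsets[i + 1]])
        records.append(TranscriptModel(
            transcript_id=f"t{i:0{width}d}", gene_id=f"g{i:0{width}d}",
            cds="ATG" + body + _STOPS[stops[i]], has_stop=True))
    return Transcriptome(records)


# ---------------------------------------------------------------------------
# Neutral simulation
# ---------------------------------------------------------------------------

def _event_index(transcriptome: Transcriptome):
    """Cached (order, boundaries) of transcriptome events sorted by SSB7 class."""
    cache = getattr(transcriptome, "_event_cache", None)
    if cache is not None:
        return cache
    arr = transcriptome._ensure_arrays()
    cls_flat = arr["cls7"].reshape(-1)
    order = np.argsort(cls_flat, kind="stable").astype(np.int64)
    bounds = np.searchsorted(cls_flat[order], np.arange(8))
    transcriptome._event_cache = (order, bounds)
    return transcriptome._event_cache


def _events_to_frame(transcriptome: Transcriptome, event_ids: np.ndarray,
                     samples: np.ndarray) -> pd.DataFrame:
    arr = transcriptome._ensure_arrays()
    total = arr["ref"].shape[0]
    row = event_ids // total
    gpos = event_ids % total
    tx_idx = transcriptome.position_transcript(gpos)
    cds_pos = gpos - arr["offsets"][tx_idx]
    ref = arr["ref"][gpos]
    alt = arr["alt"][row, gpos]
    syn = arr["syn"][row, gpos]
    pow_ = np.array([16, 4, 1], dtype=np.int16)
    new_codon = arr["codon"][gpos] + (alt.astype(np.int16) - ref) * pow_[
        arr["frame"][gpos]]
    from .reference import _STOP_CODON_IDX
    nonsense = np.isin(new_codon, list(_STOP_CODON_IDX))
    tx_ids = np.array(transcriptome.ids, dtype=object)
    genes = np.array([t.gene_id for t in arr["tx_list"]], dtype=object)
    return pd.DataFrame({
        "sample": samples,
        "transcript": tx_ids[tx_idx],
        "gene": genes[tx_idx],
        "cds_pos": cds_pos.astype(np.int64),
        "ref": _BASE_ARR[ref],
        "alt": _BASE_ARR[alt],
        "consequence": np.where(syn, "synonymous",
                                np.where(nonsense, "nonsense", "missense")),
        "class7": arr["cls7"][row, gpos].astype(np.int16),
    })


def simulate_neutral(cfg: SimulationConfig, transcriptome: Transcriptome,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a neutral cohort of SNVs under the configured signature.

    Returns an annotated mutation frame (consequence and SSB7 class filled);
    deterministic given (config, seed).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    probs = cfg.probs_array()
    if cfg.n_mutations == 0:
        return _events_to_frame(transcriptome, np.array([], dtype=np.int64),
                                np.array([], dtype=object))
    order, bounds = _event_index(transcriptome)
    avail = (bounds[1:] - bounds[:-1])[:7] > 0
    if not avail.all() and probs[~avail].sum() > 0:
        logger.warning("simulate_neutral: classes %s have no eligible "
                       "positions; their mass is redistributed",
                       [SSB7_LABELS[i] for i in np.flatnonzero(~avail)])
        probs = np.where(avail, probs, 0.0)
        probs = probs / probs.sum()
    per_class = rng.multinomial(cfg.n_mutations, probs)
    ids = []
    for k, ck in enumerate(per_class):
        if ck == 0:
            continue
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        ids.append(order[rng.integers(lo, hi, size=ck)])
    event_ids = np.concatenate(ids) if ids else np.array([], dtype=np.int64)
    n_samples = cfg.n_samples or max(1, cfg.n_mutations // 150)
    width = len(str(max(n_samples - 1, 1)))
    sample_idx = rng.integers(0, n_samples, size=event_ids.size)
    samples = np.array([f"S{i:0{width}d}" for i in range(n_samples)],
                       dtype=object)[sample_idx]
    return _events_to_frame(transcriptome, event_ids, samples)


# ---------------------------------------------------------------------------
# Selection injection
# ---------------------------------------------------------------------------

def impose_selection(neutral: pd.DataFrame, targets: Mapping[str, float],
                     transcriptome: Transcriptome,
                     seed: int | np.random.Generator = 0,
                     class_probs: Mapping[str, float] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject per-gene selection into a neutral cohort.

    For each targeted gene, non-synonymous mutations are independently
    retained with probability min(omega, 1); for omega > 1 additional
    non-synonymous mutations are drawn from the gene's own non-synonymous
    event pool (weighted by the signature, i.e. the same conditional law as
    the neutral generator) so the expected non-synonymous count becomes
    omega times the neutral expectation.  Synonymous mutations are never
    touched.  Returns the modified cohort and a truth table.
    """
    for g, w in targets.items():
        if w < 0:
            raise ConfigError(f"negative omega {w} for gene {g}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    probs = np.array([
        (class_probs or DEFAULT_CLASS_PROBS).get(lab, 0.0)
        for lab in SSB7_LABELS])
    arr = transcriptome._ensure_arrays()
    order, bounds = _event_index(transcriptome)
    class_sizes = (bounds[1:] - bounds[:-1])[:7].astype(float)

    nonsyn = neutral["consequence"].isin(mut.NON_SILENT).to_numpy()
    gene_arr = neutral["gene"].to_numpy()
    drop = np.zeros(len(neutral), dtype=bool)
    extra_frames = []
    truth_rows = []
    gene_of_tx = {t.transcript_id: t.gene_id for t in arr["tx_list"]}
    tx_of_gene: dict[str, list[str]] = {}
    for tid, gid in gene_of_tx.items():
        tx_of_gene.setdefault(gid, []).append(tid)

    for gene, omega in targets.items():
        in_gene = gene_arr == gene
        idx = np.flatnonzero(in_gene & nonsyn)
        n_pre = idx.size
        n_post = n_pre
        if omega < 1:
            keep = rng.random(n_pre) < omega
            drop[idx[~keep]] = True
            n_post = int(keep.sum())
        elif omega > 1:
            n_extra = rng.poisson((omega - 1) * n_pre)
            if n_extra > 0:
                ev = _gene_nonsyn_events(transcriptome, tx_of_gene.get(gene, []))
                if ev.size:
                    total = arr["ref"].shape[0]
                    cls = arr["cls7"].reshape(-1)[ev]
                    wts = probs[cls] / class_sizes[cls]
                    wts = wts / wts.sum()
                    chosen = rng.choice(ev, size=n_extra, p=wts)
                    samp = neutral["sample"].sample(
                        n=n_extra, replace=True,
                        random_state=int(rng.integers(2**31))).to_numpy() \
                        if len(neutral) else np.array(["S0"] * n_extra)
                    extra_frames.append(_events_to_frame(
                        transcriptome, chosen, samp))
                    n_post = n_pre + n_extra
        truth_rows.append((gene, float(omega),
                           "negative" if omega < 1 else
                           ("positive" if omega > 1 else "neutral"),
                           n_pre, n_post))
    out = neutral[~drop]
    if extra_frames:
        out = pd.concat([out] + extra_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["gene", "omega", "true_label",
                                              "n_nonsyn_pre", "n_nonsyn_post"])
    return out.reset_index(drop=True), truth


def _gene_nonsyn_events(transcriptome: Transcriptome,
                        transcript_ids: list[str]) -> np.ndarray:
    arr = transcriptome._ensure_arrays()
    total = arr["ref"].shape[0]
    ids = []
    for tid in transcript_ids:
        i = transcriptome.index_of(tid)
        lo, hi = int(arr["offsets"][i]), int(arr["offsets"][i + 1])
        for row in range(3):
            pos = np.arange(lo, hi)[~arr["syn"][row, lo:hi]]
            ids.append(row * total + pos)
    return np.concatenate(ids) if ids else np.array([], dtype=np.int64)


def make_selection_panel(transcriptome: Transcriptome, n_panel: int,
                         omegas: Sequence[float],
                         seed: int | np.random.Generator = 0
                         ) -> dict[str, float]:
    """Draw a panel of genes and assign omegas cycling through ``omegas``.

    Cycling balances the panel across the omega grid, so recall is an even
    average over selection strengths.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = sorted({t.gene_id for t in transcriptome.transcripts.values()})
    if n_panel > len(genes):
        raise ConfigError(f"panel of {n_panel} exceeds {len(genes)} genes")
    chosen = rng.choice(len(genes), size=n_panel, replace=False)
    return {genes[g]: float(omegas[i % len(omegas)])
            for i, g in enumerate(np.sort(chosen))}


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

def run_pipeline(df_or_path, transcriptome: Transcriptome,
                 system: str = "SSB7", q_threshold: float = 0.1,
                 spectra=None) -> pd.DataFrame:
    """Annotate (if needed) and run the per-gene selection scan."""
    if isinstance(df_or_path, (str, Path)):
        df = mut.read_mutations(df_or_path)
    else:
        df = df_or_path
    if "consequence" not in df.columns:
        df = mut.annotate_mutations(df, transcriptome)
    return selection.gene_selection_table(
        df, transcriptome, system=system, q_threshold=q_threshold,
        spectra=spectra)


def score_calls(results: pd.DataFrame, truth: pd.DataFrame,
                direction: str = "negative") -> dict:
    """Precision/recall of called genes against simulation truth."""
    true_set = set(truth.loc[truth["true_label"] == direction, "gene"])
    called = set(results.loc[results["label"] == direction, "gene"])
    tp = len(called & true_set)
    fp = len(called - true_set)
    fn = len(true_set - called)
    return {
        "direction": direction, "tp": tp, "fp": fp, "fn": fn,
        "n_true": len(true_set), "n_called": len(called),
        "recall": tp / (tp + fn) if true_set else float("nan"),
        "precision": tp / (tp + fp) if called else float("nan"),
    }


def benchmark_recall(dataset_sizes: Sequence[int],
                     transcriptome: Transcriptome,
                     targets: Mapping[str, float],
                     class_probs: Mapping[str, float] | None = None,
                     q_threshold: float = 0.1,
                     seeds: Sequence[int] = (0,),
                     io_roundtrip: bool = False,
                     workdir: str | Path | None = None,
                     system: str = "SSB7") -> pd.DataFrame:
    """Simulate, run the full pipeline, and score precision/recall.

    One row per (dataset size, seed, selection direction).  With
    ``io_roundtrip`` the simulated cohort is written as a MAF-dialect TSV and
    re-read through the standard ingestion/annotation path, exercising the
    pipeline end to end.
    """
    class_probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    spectra = count_sites_by_gene(transcriptome, system)
    directions = sorted({("negative" if w < 1 else "positive")
                         for w in targets.values() if w != 1}) or ["negative"]
    rows = []
    for size in dataset_sizes:
        for seed in seeds:
            rng = np.random.default_rng(seed)
            cfg = SimulationConfig(n_mutations=int(size),
                                   class_probs=class_probs, seed=seed)
            neutral = simulate_neutral(cfg, transcriptome, rng)
            cohort, truth = impose_selection(neutral, targets, transcriptome,
                                             rng, class_probs)
            if io_roundtrip:
                import tempfile
                wd = Path(workdir) if workdir else Path(tempfile.mkdtemp())
                maf = wd / f"sim_{size}_{seed}.maf.tsv"
                mut.write_maf(cohort, maf)
                cohort = mut.annotate_mutations(mut.read_mutations(maf),
                                                transcriptome)
                maf.unlink(missing_ok=True)
            results = run_pipeline(cohort, transcriptome, system=system,
                                   q_threshold=q_threshold, spectra=spectra)
            for direction in directions:
                sc = score_calls(results, truth, direction)
                sc.update(size=int(size), seed=int(seed))
                rows.append(sc)
    return pd.DataFrame(rows)
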