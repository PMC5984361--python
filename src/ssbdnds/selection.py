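"""SSB correction and dN/dS selection inference.

The somatic substitution bias (SSB) correction reweights the synonymous and
non-synonymous site counts of every gene by the fold change between the
observed frequency of each substitution class in the cohort and the expected
frequency implied by the class's share of all sites in the transcriptome.
After correction, the per-gene corrected totals Na' and Ns' carry the
cohort's mutational signature, so dN = n/Na' and dS = s/Ns' are comparable
and their ratio is a signature-free estimate of selection: dN/dS > 1 marks
positive selection, < 1 negative (purifying) selection.

Significance rests on the passenger-synonymous assumption — synonymous
somatic mutations are neutral passengers — which fixes the expected split of
a gene's n + s mutations between the two categories at
pi = Na'/(Na' + Ns').  Each gene is tested with a two-sided exact binomial
test of n successes in n + s trials against pi, followed by
Benjamini-Hochberg FDR control (default Q < 0.1).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import mutations as mut
from .errors import (
    DegenerateSites,
    EmptySpectrum,
    NoMutations,
    SystemMismatch,
)
from .reference import (
    N_CLASSES,
    SSB7_LABELS,
    SiteSpectrum,
    Transcriptome,
    count_sites_by_gene,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("gene", "n", "s", "na_corr", "ns_corr", "dn", "ds", "dnds",
                  "dnds_defined", "ci_low", "ci_high", "p", "q", "label")


# ---------------------------------------------------------------------------
# Observed / expected class frequencies and correction weights
# ---------------------------------------------------------------------------

def observed_spectrum(class_col: Iterable[int], system: str = "SSB7"
                      ) -> np.ndarray:
    """Mutation counts per substitution class."""
    k = N_CLASSES[system]
    arr = np.asarray(list(class_col) if not isinstance(class_col, np.ndarray)
                     else class_col, dtype=np.int64)
    arr = arr[arr >= 0]
    return np.bincount(arr, minlength=k).astype(float)


def expected_frequencies(spectrum_sum: SiteSpectrum) -> np.ndarray:
    """Expected class frequencies from total (Na_k + Ns_k) site shares."""
    tot = spectrum_sum.na + spectrum_sum.ns
    denom = tot.sum()
    if denom <= 0:
        raise EmptySpectrum("site spectrum sums to zero")
    return tot / denom


def fold_change_weights(observed_counts: np.ndarray,
                        expected: np.ndarray) -> np.ndarray:
    """Fold change of observed over expected class frequencies.

    Classes with zero observed mutations get weight 0 (they then contribute
    no corrected sites, matching their zero contribution to the counts);
    more than two empty classes triggers a warning since the correction then
    discards a substantial share of sites.
    """
    observed_counts = np.asarray(observed_counts, dtype=float)
    total = observed_counts.sum()
    if total <= 0:
        raise NoMutations("observed spectrum has no mutations")
    freq = observed_counts / total
    w = np.zeros_like(freq)
    nz = observed_counts > 0
    if np.any(nz & (expected <= 0)):
        raise EmptySpectrum("observed mutations in a class with zero sites")
    w[nz] = freq[nz] / expected[nz]
    n_empty = int((~nz).sum())
    if n_empty > 2:
        logger.warning("fold_change_weights: %d classes unobserved "
                       "(their sites drop out of the correction)", n_empty)
    return w


def corrected_sites(spec: SiteSpectrum, w: np.ndarray) -> tuple[float, float]:
    """SSB-corrected site totals (Na', Ns') = (sum w_k Na_k, sum w_k Ns_k)."""
    w = np.asarray(w, dtype=float)
    if w.shape != spec.na.shape:
        raise SystemMismatch(
            f"weights have {w.shape[0]} classes, spectrum {spec.na.shape[0]}")
    return float(w @ spec.na), float(w @ spec.ns)


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

def gene_dnds(n: int, s: int, na_corr: float, ns_corr: float
              ) -> tuple[float, float, float, bool]:
    """(dN, dS, dN/dS, defined-flag) from counts and corrected sites."""
    if na_corr <= 0 or ns_corr <= 0:
        raise DegenerateSites(f"corrected sites Na'={na_corr}, Ns'={ns_corr}")
    dn = n / na_corr
    ds = s / ns_corr
    if s == 0:
        return dn, ds, math.nan, False
    return dn, ds, dn / ds, True


def neutrality_test(n: int, s: int, na_corr: float, ns_corr: float) -> float:
    """Two-sided exact binomial test of the passenger-synonymous null.

    Under neutrality the n + s mutations of a gene split binomially between
    non-silent and silent with success probability pi = Na'/(Na' + Ns').
    Two-sidedness sums all outcomes whose point probability does not exceed
    that of the observed outcome.
    """
    if n + s == 0:
        raise NoMutations("gene with no mutations reached the test")
    if na_corr <= 0 or ns_corr <= 0:
        raise DegenerateSites(f"corrected sites Na'={na_corr}, Ns'={ns_corr}")
    pi = na_corr / (na_corr + ns_corr)
    return float(stats.binomtest(n, n + s, pi).pvalue)


def dnds_confidence_interval(n: int, s: int, na_corr: float, ns_corr: float,
                             level: float = 0.95
                             ) -> tuple[float, float]:
    """Normal-approximation CI for dN/dS on the log-ratio scale.

    CI = exp(log(dN/dS) +/- z * sqrt(1/n + 1/s)); undefined (NaN, NaN) when
    either count is zero.
    """
    if n == 0 or s == 0:
        return math.nan, math.nan
    dn, ds, dnds, _ = gene_dnds(n, s, na_corr, ns_corr)
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / n + 1 / s)
    return float(dnds * math.exp(-z * se)), float(dnds * math.exp(z * se))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fdr_classify(results: pd.DataFrame, q_threshold: float = 0.1
                 ) -> pd.DataFrame:
    """Add BH-adjusted Q values and selection labels to a result table.

    A gene is labelled ``positive`` when Q < threshold and dN/dS > 1,
    ``negative`` when Q < threshold and dN/dS < 1, else ``neutral``.  Genes
    with undefined dN/dS (s = 0) can only be positive (their excess is
    non-silent by construction) or neutral.
    """
    out = results.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = out["q"] < q_threshold
    dnds = out["dnds"].to_numpy()
    defined = out["dnds_defined"].to_numpy(dtype=bool)
    label = np.full(len(out), "neutral", dtype=object)
    label[sig & ((defined & (dnds > 1)) | ~defined)] = "positive"
    label[sig & defined & (dnds < 1)] = "negative"
    out["label"] = label
    return out


# ---------------------------------------------------------------------------
# Cohort-level drivers
# ---------------------------------------------------------------------------

def cohort_weights(df: pd.DataFrame, spectra: Mapping[str, SiteSpectrum],
                   system: str = "SSB7") -> np.ndarray:
    """Cohort-level SSB correction weights from all mutations together."""
    col = "class7" if system == "SSB7" else "class192"
    observed = observed_spectrum(df[col].to_numpy(), system)
    total = SiteSpectrum.zeros(system)
    for spec in spectra.values():
        total = total + spec
    return fold_change_weights(observed, expected_frequencies(total))


def gene_selection_table(df: pd.DataFrame, transcriptome: Transcriptome,
                         system: str = "SSB7", scope: str = "cohort",
                         q_threshold: float = 0.1,
                         blocklist: set[str] | None = None,
                         spectra: Mapping[str, SiteSpectrum] | None = None,
                         gene_filters: bool = True) -> pd.DataFrame:
    """Full per-gene selection scan over an annotated cohort.

    ``scope`` selects where observed class frequencies are measured:
    ``"cohort"`` (default) pools all mutations and applies one weight vector
    to every gene; ``"gene"`` recomputes weights per gene from that gene's
    own mutations (noisy for sparsely mutated genes).
    """
    if scope not in ("cohort", "gene"):
        raise ValueError(f"unknown scope {scope!r}")
    df = df[df["consequence"].isin(("synonymous", "missense", "nonsense"))]
    if df.empty:
        raise NoMutations("no coding SNVs in cohort")
    if spectra is None:
        spectra = count_sites_by_gene(transcriptome, system)
    if gene_filters:
        df, _ = mut.apply_gene_filters(df, transcriptome, spectra, blocklist)
        if df.empty:
            raise NoMutations("all genes removed by gene-level filters")
    col = "class7" if system == "SSB7" else "class192"
    w_cohort = cohort_weights(df, spectra, system)
    expected = None
    if scope == "gene":
        total = SiteSpectrum.zeros(system)
        for sp in spectra.values():
            total = total + sp
        expected = expected_frequencies(total)

    counts = mut.gene_counts(df, transcriptome)
    gene_col = df["transcript"].map(transcriptome.gene_of)
    rows = []
    for gene, sub in df.groupby(gene_col.to_numpy()):
        spec = spectra[gene]
        if scope == "gene":
            w = fold_change_weights(
                observed_spectrum(sub[col].to_numpy(), system), expected)
        else:
            w = w_cohort
        na_c, ns_c = corrected_sites(spec, w)
        n, s = int(counts.loc[gene, "n"]), int(counts.loc[gene, "s"])
        if na_c <= 0 or ns_c <= 0:
            logger.warning("gene %s: degenerate corrected sites, skipped", gene)
            continue
        dn, ds, dnds, defined = gene_dnds(n, s, na_c, ns_c)
        p = neutrality_test(n, s, na_c, ns_c)
        lo, hi = dnds_confidence_interval(n, s, na_c, ns_c)
        rows.append((gene, n, s, na_c, ns_c, dn, ds, dnds, defined, lo, hi, p))
    res = pd.DataFrame(rows, columns=["gene", "n", "s", "na_corr", "ns_corr",
                                      "dn", "ds", "dnds", "dnds_defined",
                                      "ci_low", "ci_high", "p"])
    return fdr_classify(res, q_threshold)


def global_dnds(df: pd.DataFrame, transcriptome: Transcriptome,
                system: str = "SSB7",
                spectra: Mapping[str, SiteSpectrum] | None = None) -> dict:
    """Exome-wide dN/dS: the whole transcriptome treated as a single gene."""
    df = df[df["consequence"].isin(("synonymous", "missense", "nonsense"))]
    if df.empty:
        raise NoMutations("empty cohort")
    if spectra is None:
        spectra = count_sites_by_gene(transcriptome, system)
    total = SiteSpectrum.zeros(system)
    for spec in spectra.values():
        total = total + spec
    col = "class7" if system == "SSB7" else "class192"
    w = fold_change_weights(observed_spectrum(df[col].to_numpy(), system),
                            expected_frequencies(total))
    na_c, ns_c = corrected_sites(total, w)
    n = int(df["consequence"].isin(mut.NON_SILENT).sum())
    s = int((df["consequence"] == "synonymous").sum())
    dn, ds, dnds, defined = gene_dnds(n, s, na_c, ns_c)
    lo, hi = dnds_confidence_interval(n, s, na_c, ns_c)
    return {"n": n, "s": s, "na_corr": na_c, "ns_corr": ns_c, "dn": dn,
            "ds": ds, "dnds": dnds, "dnds_defined": defined,
            "ci_low": lo, "ci_high": hi,
            "p": neutrality_test(n, s, na_c, ns_c)}


def pan_cancer_combine(per_cohort: Sequence[Mapping]) -> dict:
    """Combine per-cohort corrected sites weighted by mutation share.

    Each element supplies ``m`` (post-filter mutation count), ``na_corr``,
    ``ns_corr``, ``n`` and ``s``.  Corrected sites are averaged with weights
    f_t = m_t / sum(m); counts are summed; dN/dS and the neutrality test are
    recomputed on the combined quantities.
    """
    if not per_cohort:
        raise NoMutations("no cohorts supplied")
    m = np.array([c["m"] for c in per_cohort], dtype=float)
    if m.sum() <= 0:
        raise NoMutations("zero total mutations across cohorts")
    f = m / m.sum()
    na = float(sum(fi * c["na_corr"] for fi, c in zip(f, per_cohort)))
    ns = float(sum(fi * c["ns_corr"] for fi, c in zip(f, per_cohort)))
    n = int(sum(c["n"] for c in per_cohort))
    s = int(sum(c["s"] for c in per_cohort))
    dn, ds, dnds, defined = gene_dnds(n, s, na, ns)
    lo, hi = dnds_confidence_interval(n, s, na, ns)
    return {"n": n, "s": s, "na_corr": na, "ns_corr": ns, "dn": dn, "ds": ds,
            "dnds": dnds, "dnds_defined": defined, "ci_low": lo, "ci_high": hi,
            "p": neutrality_test(n, s, na, ns)}


def write_results(res: pd.DataFrame, path, header_comments=None) -> None:
    """Write a per-gene result table as TSV with optional '#' header lines."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        res.to_csv(fh, sep="\t", index=False, float_format="%.6g")
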