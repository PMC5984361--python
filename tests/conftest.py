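import numpy as np
import pytest

import ssbdnds as s


@pytest.fixture(scope="session")
def toy_tx():
    """Small deterministic toy transcriptome (30 genes, ~1.5 kb each)."""
    return s.make_toy_transcriptome(30, seed=7)


@pytest.fixture(scope="session")
def toy_spectra(toy_tx):
    return s.count_sites_by_gene(toy_tx)


@pytest.fixture(scope="session")
def neutral_cohort(toy_tx):
    """A neutral cohort of 30k SNVs over the toy transcriptome."""
    cfg = s.SimulationConfig(n_mutations=30000, seed=11)
    return s.simulate_neutral(cfg, toy_tx)


def brute_force_site_counts(cds: str, has_stop: bool):
    """Independent site-count oracle: loop positions x 3 alternates,
    translate both codons with biopython, classify with the scalar rule."""
    from Bio.Seq import Seq

    counted = len(cds) - 3 if has_stop else len(cds)
    na = {lab: 0.0 for lab in s.SSB7_LABELS}
    ns = {lab: 0.0 for lab in s.SSB7_LABELS}
    for pos in range(counted):
        ref = cds[pos]
        five = cds[pos - 1] if pos > 0 else None
        three = cds[pos + 1] if pos + 1 < len(cds) else None
        ci = pos // 3
        codon = cds[3 * ci:3 * ci + 3]
        for alt in "ACGT":
            if alt == ref:
                continue
            lab = s.classify_substitution7(ref, alt, five, three)
            alt_codon = codon[:pos % 3] + alt + codon[pos % 3 + 1:]
            if str(Seq(codon).translate()) == str(Seq(alt_codon).translate()):
                ns[lab] += 1 / 3
            else:
                na[lab] += 1 / 3
    return na, ns
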