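"""Transcript models, substitution-class systems, and site counting.

Selection on somatic point mutations is measured against the opportunity for
synonymous and non-synonymous change offered by a coding sequence.  This
module loads CDS records, defines the two substitution-class systems used for
the somatic substitution bias (SSB) correction — seven collapsed classes
including CpG transitions (SSB7) and the 192 trinucleotide-context/strand
classes (SSB192) — and counts fractional synonymous (Ns) and non-synonymous
(Na) sites per class per transcript with the approximate (1/3-site-per-change)
convention, so that Na + Ns summed over classes equals the counted CDS length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    ContextUnavailable,
    EmptyTranscript,
    InvalidBase,
    InvalidSubstitution,
    InvalidTranscript,
)

logger = logging.getLogger(__name__)

# Base encoding: A=0, C=1, G=2, T=3; complement is 3 - code.  Code 4 marks an
# unknown neighbor at a sequence boundary.
BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
UNKNOWN = 4

SSB7_LABELS = ("A>T", "A>C", "A>G", "C>A", "C>T", "C>G", "CpG>N")
CPG_CLASS = 6
N_CLASSES = {"SSB7": 7, "SSB192": 192}

# Pyrimidine-centered substitutions in COSMIC order, used by SSB192.
_PYR_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_PYR_SUB_INDEX = {s: i for i, s in enumerate(_PYR_SUBS)}

_STOP_CODONS = ("TAA", "TAG", "TGA")

# 64-entry amino-acid table indexed by 16*b0 + 4*b1 + b2.
_AA = np.array(
    [str(Seq(a + b + c).translate()) for a in BASES for b in BASES for c in BASES]
)
_STOP_CODON_IDX = {16 * _BASE_CODE[c[0]] + 4 * _BASE_CODE[c[1]] + _BASE_CODE[c[2]]
                   for c in _STOP_CODONS}


def _code(base: str) -> int:
    try:
        return _BASE_CODE[base]
    except (KeyError, TypeError):
        raise InvalidBase(f"invalid nucleotide {base!r}; expected one of A,C,G,T")


def _complement(base: str) -> str:
    return BASES[3 - _code(base)]


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A coding sequence in CDS space.

    Parameters
    ----------
    transcript_id, gene_id
        Identifiers; when no transcript-to-gene map is supplied the gene id
        defaults to the transcript id (one transcript per gene).
    cds
        Uppercase A/C/G/T string whose length is a multiple of 3.
    has_stop
        Whether the final codon is a terminal stop codon.  The terminal stop
        is excluded from site counting.
    """

    transcript_id: str
    gene_id: str
    cds: str
    has_stop: bool = True

    def __post_init__(self):
        if len(self.cds) == 0:
            raise EmptyTranscript(f"{self.transcript_id}: empty CDS")
        if len(self.cds) % 3:
            raise InvalidTranscript(
                f"{self.transcript_id}: CDS length {len(self.cds)} not a multiple of 3"
            )
        if set(self.cds) - set(BASES):
            bad = sorted(set(self.cds) - set(BASES))
            raise InvalidTranscript(
                f"{self.transcript_id}: non-ACGT characters {bad}"
            )
        codons = [self.cds[i:i + 3] for i in range(0, len(self.cds), 3)]
        internal = codons[:-1] if self.has_stop else codons
        if any(c in _STOP_CODONS for c in internal):
            raise InvalidTranscript(
                f"{self.transcript_id}: internal stop codon"
            )
        if self.has_stop and codons[-1] not in _STOP_CODONS:
            raise InvalidTranscript(
                f"{self.transcript_id}: has_stop set but final codon "
                f"{codons[-1]} is not a stop codon"
            )

    @property
    def counted_length(self) -> int:
        """Number of CDS positions entering site counts (terminal stop excluded)."""
        return len(self.cds) - 3 if self.has_stop else len(self.cds)

    @property
    def protein_length(self) -> int:
        return self.counted_length // 3

    def codes(self) -> np.ndarray:
        """CDS as an int8 array (A=0, C=1, G=2, T=3)."""
        raw = np.frombuffer(self.cds.encode(), dtype=np.uint8)
        return _ASCII_CODE[raw]


# ASCII lookup for fast string-to-code conversion
_ASCII_CODE = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_CODE.items():
    _ASCII_CODE[ord(_b)] = _i


# ---------------------------------------------------------------------------
# Substitution-class systems
# ---------------------------------------------------------------------------

def classify_substitution7(ref: str, alt: str, five_prime: str | None,
                           three_prime: str | None) -> str:
    """Assign a point substitution to one of the seven SSB7 classes.

    Strand-collapsed: purine-reference changes are read through the reverse
    complement (T>x ≡ A>x̄, G>x ≡ C>x̄).  Any change whose reference base sits
    in a CpG dinucleotide — the C of a 5'-CG-3' on the coding strand, or the
    G of a CG (the C on the template strand) — is classed ``CpG>N`` regardless
    of the alternate allele.  Unknown neighbors (``None`` or ``"N"``) are
    treated as non-C/non-G, so boundary positions never receive a CpG call.
    """
    r, a = _code(ref), _code(alt)
    if r == a:
        raise InvalidSubstitution(f"ref and alt are both {ref!r}")
    five = five_prime if five_prime not in (None, "N", "n") else None
    three = three_prime if three_prime not in (None, "N", "n") else None
    if five is not None:
        _code(five)  # validate
    if three is not None:
        _code(three)
    if (ref == "C" and three == "G") or (ref == "G" and five == "C"):
        return "CpG>N"
    if ref in ("T", "G"):
        ref, alt = _complement(ref), _complement(alt)
    return f"{ref}>{alt}"


def classify_substitution192(ref: str, alt: str, five_prime: str,
                             three_prime: str) -> int:
    """Assign a substitution to one of the 192 context/strand classes.

    The class index encodes (pyrimidine-centered substitution, 5' base,
    3' base, strand): purine-reference triples are reverse-complemented to
    the pyrimidine-centered form (the flanks swap and complement) and
    flagged as the opposite strand.  Index layout::

        index = strand * 96 + substitution * 16 + five * 4 + three

    with substitutions in the order C>A, C>G, C>T, T>A, T>C, T>G and flank
    bases in A, C, G, T order.  Both neighbors must be known.
    """
    r, a = _code(ref), _code(alt)
    if r == a:
        raise InvalidSubstitution(f"ref and alt are both {ref!r}")
    if five_prime in (None, "N", "n") or three_prime in (None, "N", "n"):
        raise ContextUnavailable(
            "SSB192 classification requires both flanking bases"
        )
    f, t = _code(five_prime), _code(three_prime)
    strand = 0
    if ref in ("A", "G"):  # purine reference: read the other strand
        r, a = 3 - r, 3 - a
        f, t = 3 - t, 3 - f
        strand = 1
    sub = _PYR_SUB_INDEX[f"{BASES[r]}>{BASES[a]}"]
    return strand * 96 + sub * 16 + f * 4 + t


def ssb192_tuple(index: int) -> tuple[str, str, str, int]:
    """Decode an SSB192 index to (substitution, 5' base, 3' base, strand)."""
    strand, rest = divmod(index, 96)
    sub, rest = divmod(rest, 16)
    f, t = divmod(rest, 4)
    return _PYR_SUBS[sub], BASES[f], BASES[t], strand


def _build_lut7() -> np.ndarray:
    """(ref, alt, five, three) -> SSB7 class index; neighbor code 4 = unknown."""
    lut = np.full((4, 4, 5, 5), -1, dtype=np.int8)
    neighbors = list(BASES) + [None]
    label_idx = {lab: i for i, lab in enumerate(SSB7_LABELS)}
    for ri, ref in enumerate(BASES):
        for ai, alt in enumerate(BASES):
            if ri == ai:
                continue
            for fi, five in enumerate(neighbors):
                for ti, three in enumerate(neighbors):
                    lut[ri, ai, fi, ti] = label_idx[
                        classify_substitution7(ref, alt, five, three)
                    ]
    return lut


def _build_lut192() -> np.ndarray:
    lut = np.full((4, 4, 4, 4), -1, dtype=np.int16)
    for ri, ref in enumerate(BASES):
        for ai, alt in enumerate(BASES):
            if ri == ai:
                continue
            for fi, five in enumerate(BASES):
                for ti, three in enumerate(BASES):
                    lut[ri, ai, fi, ti] = classify_substitution192(
                        ref, alt, five, three
                    )
    return lut


LUT7 = _build_lut7()
LUT192 = _build_lut192()


# ---------------------------------------------------------------------------
# Site spectra
# ---------------------------------------------------------------------------

@dataclass
class SiteSpectrum:
    """Fractional non-synonymous (``na``) and synonymous (``ns``) site counts
    per substitution class, under the 1/3-site-per-possible-change convention.
    """

    system: str
    na: np.ndarray
    ns: np.ndarray

    def __post_init__(self):
        k = N_CLASSES[self.system]
        self.na = np.asarray(self.na, dtype=float)
        self.ns = np.asarray(self.ns, dtype=float)
        if self.na.shape != (k,) or self.ns.shape != (k,):
            raise ValueError(f"{self.system} spectrum needs {k} classes")

    @classmethod
    def zeros(cls, system: str) -> "SiteSpectrum":
        k = N_CLASSES[system]
        return cls(system, np.zeros(k), np.zeros(k))

    @property
    def total_na(self) -> float:
        return float(self.na.sum())

    @property
    def total_ns(self) -> float:
        return float(self.ns.sum())

    @property
    def total(self) -> float:
        return self.total_na + self.total_ns

    def __add__(self, other: "SiteSpectrum") -> "SiteSpectrum":
        if self.system != other.system:
            from .errors import SystemMismatch
            raise SystemMismatch(f"{self.system} vs {other.system}")
        return SiteSpectrum(self.system, self.na + other.na, self.ns + other.ns)


# ---------------------------------------------------------------------------
# Transcriptome container with vectorized per-position tables
# ---------------------------------------------------------------------------

class Transcriptome:
    """An ordered set of transcript models with cached position-level tables.

    The cache concatenates all counted CDS positions (terminal stop codons
    excluded) and stores, per position, the reference code, both neighbor
    codes, and the codon index, plus per-event (position x 3 alternates)
    class and synonymity tables used by site counting, mutation annotation,
    and the simulator.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise InvalidTranscript(f"duplicate transcript {tx.transcript_id}")
            self.transcripts[tx.transcript_id] = tx
        self._ids = list(self.transcripts)
        self._index = {t: i for i, t in enumerate(self._ids)}
        self._arrays: dict | None = None

    # -- basic mapping -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    @property
    def ids(self) -> list[str]:
        return self._ids

    def index_of(self, transcript_id: str) -> int:
        return self._index[transcript_id]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    # -- construction --------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path,
                   gene_map: Mapping[str, str] | str | Path | None = None,
                   has_stop: bool | None = None) -> "Transcriptome":
        """Load CDS records from FASTA (header = transcript id).

        ``gene_map`` may be a mapping or a 2-column TSV path
        (transcript_id <tab> gene_id); absent transcripts keep their own id
        as gene id.  ``has_stop`` of ``None`` auto-detects a terminal stop
        codon per record.
        """
        if gene_map is not None and not isinstance(gene_map, Mapping):
            gene_map = load_gene_map(gene_map)
        gene_map = gene_map or {}
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            cds = str(rec.seq).upper()
            stop = (cds[-3:] in _STOP_CODONS) if has_stop is None else has_stop
            records.append(TranscriptModel(
                transcript_id=rec.id,
                gene_id=gene_map.get(rec.id, rec.id),
                cds=cds,
                has_stop=stop,
            ))
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tx in self.transcripts.values():
                fh.write(f">{tx.transcript_id}\n")
                for i in range(0, len(tx.cds), 60):
                    fh.write(tx.cds[i:i + 60] + "\n")

    # -- cached global tables -----------------------------------------------
    def _ensure_arrays(self) -> dict:
        if self._arrays is not None:
            return self._arrays
        txs = list(self.transcripts.values())
        counted = np.array([t.counted_length for t in txs], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(counted)])
        total = int(offsets[-1])

        ref = np.empty(total, dtype=np.int8)
        five = np.empty(total, dtype=np.int8)
        three = np.empty(total, dtype=np.int8)
        codon = np.empty(total, dtype=np.int16)
        frame = np.empty(total, dtype=np.int8)
        for i, tx in enumerate(txs):
            arr = tx.codes()
            lc = tx.counted_length
            sl = slice(int(offsets[i]), int(offsets[i + 1]))
            ref[sl] = arr[:lc]
            fv = np.empty(lc, dtype=np.int8)
            fv[0] = UNKNOWN
            fv[1:] = arr[:lc - 1]
            five[sl] = fv
            th = np.empty(lc, dtype=np.int8)
            th[:-1] = arr[1:lc]
            # the last counted position's 3' neighbor is the first base of
            # the terminal stop codon when one is present
            th[-1] = arr[lc] if tx.has_stop else UNKNOWN
            three[sl] = th
            pos = np.arange(lc)
            ci = pos // 3
            frame[sl] = (pos % 3).astype(np.int8)
            b = arr[:3 * (lc // 3)].reshape(-1, 3).astype(np.int16)
            codon[sl] = (16 * b[:, 0] + 4 * b[:, 1] + b[:, 2])[ci]

        # per-event tables: 3 alternates per position
        aa_code = np.array([ord(c) for c in _AA], dtype=np.int8)
        ref_aa = aa_code[codon]
        pow_ = np.array([16, 4, 1], dtype=np.int16)
        alt = np.empty((3, total), dtype=np.int8)
        syn = np.empty((3, total), dtype=bool)
        cls7 = np.empty((3, total), dtype=np.int8)
        cls192 = np.empty((3, total), dtype=np.int16)
        for off in (1, 2, 3):
            a = ((ref + off) % 4).astype(np.int8)
            alt[off - 1] = a
            new_codon = codon + (a.astype(np.int16) - ref) * pow_[frame]
            syn[off - 1] = aa_code[new_codon] == ref_aa
            cls7[off - 1] = LUT7[ref, a, five, three]
            known = (five != UNKNOWN) & (three != UNKNOWN)
            c192 = np.full(total, -1, dtype=np.int16)
            c192[known] = LUT192[ref[known], a[known], five[known], three[known]]
            cls192[off - 1] = c192

        self._arrays = {
            "tx_list": txs,
            "counted": counted,
            "offsets": offsets,
            "ref": ref, "five": five, "three": three,
            "codon": codon, "frame": frame,
            "alt": alt, "syn": syn, "cls7": cls7, "cls192": cls192,
        }
        return self._arrays

    def global_position(self, tx_index: np.ndarray, cds_pos: np.ndarray) -> np.ndarray:
        arr = self._ensure_arrays()
        return arr["offsets"][tx_index] + cds_pos

    def position_transcript(self, gpos: np.ndarray) -> np.ndarray:
        """Map global counted positions back to transcript indices."""
        arr = self._ensure_arrays()
        return np.searchsorted(arr["offsets"], gpos, side="right") - 1


# ---------------------------------------------------------------------------
# Site counting
# ---------------------------------------------------------------------------

def count_sites(tx: TranscriptModel, system: str = "SSB7") -> SiteSpectrum:
    """Count fractional Na/Ns sites per substitution class for one transcript.

    Every counted CDS position contributes 1/3 of a site for each of its
    three possible alternate bases, to the non-synonymous tally when the
    induced codon change alters the amino acid (changes to or from stop
    included) and to the synonymous tally otherwise.  Context comes from the
    CDS itself; under SSB7 the first and last positions fall back to the
    unknown-neighbor rule (no CpG call), while under SSB192 positions lacking
    a flank are skipped entirely.
    """
    return count_sites_by_gene(Transcriptome([tx]), system)[tx.gene_id]


def count_sites_by_gene(transcriptome: Transcriptome,
                        system: str = "SSB7") -> dict[str, SiteSpectrum]:
    """Vectorized per-gene site spectra over a whole transcriptome."""
    arr = transcriptome._ensure_arrays()
    k = N_CLASSES[system]
    cls = arr["cls7"] if system == "SSB7" else arr["cls192"]
    syn = arr["syn"]
    total = arr["ref"].shape[0]
    if total == 0:
        raise EmptyTranscript("transcriptome has no counted positions")
    tx_of_pos = np.repeat(
        np.arange(len(arr["tx_list"]), dtype=np.int64), arr["counted"]
    )
    n_tx = len(arr["tx_list"])
    acc = np.zeros(n_tx * k * 2, dtype=np.float64)
    for row in range(3):
        c = cls[row].astype(np.int64)
        keep = c >= 0  # SSB192 drops flankless boundary events
        idx = (tx_of_pos[keep] * k + c[keep]) * 2 + syn[row][keep]
        acc += np.bincount(idx, minlength=n_tx * k * 2)
    acc = acc.reshape(n_tx, k, 2) / 3.0
    out: dict[str, SiteSpectrum] = {}
    for i, tx in enumerate(arr["tx_list"]):
        spec = SiteSpectrum(system, acc[i, :, 0].copy(), acc[i, :, 1].copy())
        if tx.gene_id in out:
            out[tx.gene_id] = out[tx.gene_id] + spec
        else:
            out[tx.gene_id] = spec
    return out


def load_gene_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column transcript-to-gene TSV."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InvalidTranscript(f"malformed gene-map line: {line!r}")
            out[parts[0]] = parts[1]
    return out
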