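"""Six-frame conceptual translation of nucleotide sequences.

Used to rescue genes that are present in an assembly but missing from the
predicted proteome.  Each of the six frames is translated with the standard
genetic code; segments never read through stop codons, codons containing an
ambiguous base translate to X, and fully ambiguous (all-N) codons break the
segment like a stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_COMP = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TranslatedSegment:
    """A stop-free translated stretch of one frame.

    ``start``/``end`` are a 0-based half-open nucleotide interval on the
    forward strand of the source contig; ``frame`` is +1/+2/+3 (forward) or
    -1/-2/-3 (reverse complement).
    """

    contig: str
    frame: int
    start: int
    end: int
    seq: str

    def nt_interval_of(self, aa_start: int, aa_end: int) -> tuple:
        """Forward-strand nucleotide interval of an amino-acid sub-interval."""
        if self.frame > 0:
            return self.start + 3 * aa_start, self.start + 3 * aa_end
        return self.end - 3 * aa_end, self.end - 3 * aa_start


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "*" if codon == "NNN" else "X"
    if codon in _STOPS:
        return "*"
    return _FORWARD[codon]


def six_frame_translate(
    dna: str, min_len: int = 1, contig_id: str = ""
) -> List[TranslatedSegment]:
    """All stop-free segments of length >= ``min_len`` across the six frames."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    dna = dna.upper()
    bad = set(dna) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    L = len(dna)
    segments: List[TranslatedSegment] = []
    for strand in (1, -1):
        work = dna if strand == 1 else reverse_complement(dna)
        for off in range(3):
            aa_chars: List[str] = []
            seg_start = off
            pos = off
            while pos + 3 <= L:
                aa = _translate_codon(work[pos : pos + 3])
                if aa == "*":
                    _flush(segments, aa_chars, seg_start, pos, strand, off, L,
                           contig_id, min_len)
                    aa_chars = []
                    seg_start = pos + 3
                else:
                    aa_chars.append(aa)
                pos += 3
            _flush(segments, aa_chars, seg_start, pos, strand, off, L, contig_id, min_len)
    return segments


def _flush(segments, aa_chars, seg_start, seg_end, strand, off, L, contig_id, min_len):
    if len(aa_chars) < min_len:
        return
    if strand == 1:
        start, end = seg_start, seg_end
        frame = off + 1
    else:
        start, end = L - seg_end, L - seg_start
        frame = -(off + 1)
    segments.append(TranslatedSegment(contig_id, frame, start, end, "".join(aa_chars)))
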