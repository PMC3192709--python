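"""In-silico re-implementation of the PCR/gel sizing intron survey.

A primer pair is matched against an ungapped template (forward primer on the
given strand, reverse primer as its reverse complement downstream), amplicon
sizes are computed *inclusive of both primer footprints*, and taxa are
classified intron-present/absent by comparing the amplicon to the size
expected for an intron-lacking gene.  Intron extraction and ORF measurement
complete the typing.

Amplicon length convention: the product spans from the first base of the
forward-primer footprint to the last base of the reverse-primer footprint,
both inclusive.  Published product sizes rarely state this convention; it is
the one under which an intron insertion adds exactly the intron's length to
the product.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PrimerError(ValueError):
    pass


class ExtractionError(ValueError):
    """Flanks of a putative insert fail to match the exon reference."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both primers written 5'->3' as synthesized.

    The reverse primer anneals to the sense strand's complement, so it is
    matched against the template as its reverse complement.
    """

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq:
                raise PrimerError("empty primer sequence")
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise PrimerError(f"non-IUPAC characters in primer: {sorted(bad)}")


#: Primers used in the published cox1 intron survey, exactly as synthesized.
#: cox1-3/6 amplify most of exon 2 plus a little of exon 1 (products 800 bp
#: intron-less / ~1.8 kb with intron); cox1-1/4 amplify most of exon 1
#: (750 / 1735 bp); cox1-8/10 are intron-internal sequencing primers.
PRIMER_REGISTRY: dict[str, str] = {
    "cox1-1": "AYGAMAAATCYGGTYGATGG",
    "cox1-3": "CATCTCTTTYTGTTCTTCGGT",
    "cox1-4": "ACCGRATCCAGGCAGAATGRG",
    "cox1-6": "AGCTGGAAGTTCTCCAAAAGT",
    "cox1-8": "GTAGAGTCTTATAAGGTAGT",
    "cox1-10": "TGACTACTATCAAAGTAGA",
}


def get_primer_pair(forward_name: str, reverse_name: str) -> PrimerPair:
    try:
        fwd = PRIMER_REGISTRY[forward_name]
        rev = PRIMER_REGISTRY[reverse_name]
    except KeyError as exc:
        raise PrimerError(
            f"unknown primer {exc.args[0]!r}; known: {sorted(PRIMER_REGISTRY)}"
        ) from None
    return PrimerPair(name=f"{forward_name}/{reverse_name}", forward=fwd, reverse=rev)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_matches(primer_base: str, template_base: str) -> bool:
    """Does an IUPAC primer base accept a template base?

    Template ambiguity codes other than N are treated permissively here
    (PCR convention): a match is accepted if the allowed sets intersect.
    """
    return bool(set(IUPAC[primer_base.upper()]) & set(IUPAC.get(template_base.upper(), "")))


def _match_positions(pattern: str, template: str, max_mismatches: int) -> list[int]:
    """Start positions where the IUPAC pattern matches with <= max_mismatches."""
    pattern = pattern.upper()
    template = template.upper()
    if max_mismatches == 0:
        regex = "".join(
            f"[{IUPAC[b]}]" if len(IUPAC[b]) > 1 else IUPAC[b] for b in pattern
        )
        return [m.start() for m in re.finditer(f"(?=({regex}))", template)]
    n, m = len(template), len(pattern)
    hits = []
    for start in range(n - m + 1):
        mismatches = 0
        for i in range(m):
            if not iupac_matches(pattern[i], template[start + i]):
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            hits.append(start)
    return hits


@dataclass(frozen=True)
class Amplicon:
    start: int   # 0-based, first base of forward-primer footprint
    end: int     # 0-based exclusive, past last base of reverse footprint
    length: int


def insilico_pcr(
    template: str,
    primer_pair: PrimerPair,
    max_mismatches: int = 0,
    max_product_size: int = 5000,
) -> list[Amplicon]:
    """Predict amplicons of a primer pair on an ungapped template.

    Every forward/reverse placement pair with the reverse footprint
    downstream of the forward footprint and product <= ``max_product_size``
    is reported; product length includes both primer footprints.
    """
    template = template.upper().replace("U", "T")
    if "-" in template:
        raise PrimerError("template must be ungapped")
    fwd_hits = _match_positions(primer_pair.forward, template, max_mismatches)
    rev_hits = _match_positions(
        reverse_complement(primer_pair.reverse), template, max_mismatches
    )
    rev_len = len(primer_pair.reverse)
    fwd_len = len(primer_pair.forward)
    amplicons = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + rev_len
            if r >= f + fwd_len and end - f <= max_product_size:
                amplicons.append(Amplicon(start=f, end=end, length=end - f))
    return sorted(amplicons, key=lambda a: (a.start, a.length))


def classify_presence(
    amplicon_length: int | None,
    expected_intronless_length: int,
    threshold_delta: int = 500,
    tolerance: int = 50,
) -> str:
    """Gel-sizing call: 'present', 'absent', 'ambiguous' or 'no_amplicon'.

    A product within ``tolerance`` of the intron-less expectation is called
    absent; one at least ``threshold_delta`` larger is called present
    (angiosperm cox1 introns are ~1 kb, so the default 500-bp delta
    separates the two bands unambiguously); anything else is ambiguous.
    """
    if expected_intronless_length <= 0:
        raise ValueError("expected_intronless_length must be positive")
    if amplicon_length is None:
        return "no_amplicon"
    if abs(amplicon_length - expected_intronless_length) <= tolerance:
        return "absent"
    if amplicon_length >= expected_intronless_length + threshold_delta:
        return "present"
    return "ambiguous"


def extract_intron(
    sequence_with_intron: str,
    exon_reference: str,
    insertion_point: int,
    max_flank_mismatches: int = 0,
) -> tuple[str, int]:
    """Pull out the segment inserted at ``insertion_point`` of the reference.

    ``insertion_point`` is the number of reference bases 5' of the insert
    (the insert sits between reference positions insertion_point-1 and
    insertion_point, 0-based).  Returns (intron_sequence, length); length 0
    when the sequence carries no insert.
    """
    seq = sequence_with_intron.upper().replace("U", "T")
    ref = exon_reference.upper().replace("U", "T")
    if not 0 <= insertion_point <= len(ref):
        raise ExtractionError("insertion_point outside reference")
    insert_len = len(seq) - len(ref)
    if insert_len < 0:
        raise ExtractionError("sequence shorter than exon reference")
    five = seq[:insertion_point]
    three = seq[insertion_point + insert_len:]
    mism = sum(a != b for a, b in zip(five, ref[:insertion_point]))
    mism += sum(a != b for a, b in zip(three, ref[insertion_point:]))
    if mism > max_flank_mismatches:
        raise ExtractionError(
            f"{mism} flank mismatches exceed budget {max_flank_mismatches}"
        )
    return seq[insertion_point:insertion_point + insert_len], insert_len


_STOPS = ("TAA", "TAG", "TGA")


def longest_orf(seq: str) -> tuple[int, int]:
    """Longest forward-strand ORF (ATG..stop, stop included in the length).

    Returns (start, length); ties broken by the smallest start; (0, 0) when
    no complete ORF exists.
    """
    seq = seq.upper().replace("U", "T")
    best = (0, 0)
    # first in-frame stop at or after each position, per frame
    n = len(seq)
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] in _STOPS]
        starts = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] == "ATG"]
        si = 0
        for start in starts:
            while si < len(stops) and stops[si] < start:
                si += 1
            j = si
            if j < len(stops):
                length = stops[j] + 3 - start
                if length > best[1] or (length == best[1] and start < best[0]):
                    best = (start, length)
    return best


@dataclass
class IntronCall:
    """Typing result for one taxon."""

    taxon: str
    amplicon_length: int | None
    classification: str
    intron_length: int | None = None
    orf_length: int | None = None


def survey_taxon(
    taxon: str,
    template: str,
    primer_pair: PrimerPair,
    expected_intronless_length: int,
    exon_reference: str | None = None,
    insertion_point: int | None = None,
    max_mismatches: int = 0,
    threshold_delta: int = 500,
    max_flank_mismatches: int = 0,
) -> IntronCall:
    """PCR-type one taxon and, if possible, extract its intron and ORF."""
    amps = insilico_pcr(template, primer_pair, max_mismatches=max_mismatches)
    amp_len = amps[0].length if amps else None
    call = classify_presence(amp_len, expected_intronless_length, threshold_delta)
    intron_len = orf_len = None
    if exon_reference is not None and insertion_point is not None and amp_len is not None:
        try:
            intron_seq, intron_len = extract_intron(
                template, exon_reference, insertion_point,
                max_flank_mismatches=max_flank_mismatches,
            )
        except ExtractionError:
            intron_seq, intron_len = None, None
        if intron_seq:
            orf_len = longest_orf(intron_seq)[1]
    return IntronCall(
        taxon=taxon,
        amplicon_length=amp_len,
        classification=call,
        intron_length=intron_len,
        orf_length=orf_len,
    )
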