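"""Marker defaults and run-level helpers.

The shipped marker table mirrors a four-amplicon fig-wasp design: two
overlapping COI fragments (a full-length barcode "COI-long" and a 3'
"COI-short"), Cytb, and the nuclear EF1a. Primer *sequences* are
placeholders to be replaced with the user's own primers — only their
lengths matter for the product-length arithmetic (published Folmer and
CB primer sequences are used where their lengths fit the design).
"""

from __future__ import annotations

from .model import GeneticCode, MarkerSpec

# LCO1490 / HCO2198 (Folmer): real published sequences.
LCO1490 = "GGTCAACAAATCATAAAGATATTGG"          # 25 nt
HCO2198 = "TAAACTTCAGGGTGACCAAAAAATCA"         # 26 nt
# CB1 / CB2: real published cytochrome-b primers.
CB1 = "TATGTACTACCATGAGGACAAATATC"             # 26 nt
CB2 = "ATTACACCTCCTAATTTATTAGGAAT"             # 26 nt
# Placeholder sequences of the documented lengths; replace in your config.
UEA3_PLACEHOLDER = "TATAGCATTCCCACGAATAAATAAT"  # 25 nt
EF_F_PLACEHOLDER = "GAACGTGAACGTGGTATCACSA"     # 22 nt
EF_R_PLACEHOLDER = "TTACCTGGACGGCTTTCACGRAT"    # 23 nt


def default_markers() -> list[MarkerSpec]:
    """The four shipped marker specs (COI-long, COI-short, Cytb, EF)."""
    return [
        MarkerSpec(
            name="COI-long",
            fwd_primer=LCO1490,
            rev_primer=HCO2198,
            expected_amplicon_len=658,
            min_len=None,
            max_len=None,
            genetic_code=GeneticCode.INVERTEBRATE_MITO,
            read_overlap_expected=False,
        ),
        MarkerSpec(
            name="COI-short",
            fwd_primer=UEA3_PLACEHOLDER,
            rev_primer=HCO2198,
            expected_amplicon_len=409,
            min_len=400,
            max_len=550,
            genetic_code=GeneticCode.INVERTEBRATE_MITO,
            read_overlap_expected=True,
        ),
        MarkerSpec(
            name="Cytb",
            fwd_primer=CB1,
            rev_primer=CB2,
            expected_amplicon_len=433,
            min_len=400,
            max_len=550,
            genetic_code=GeneticCode.INVERTEBRATE_MITO,
            read_overlap_expected=True,
        ),
        MarkerSpec(
            name="EF",
            fwd_primer=EF_F_PLACEHOLDER,
            rev_primer=EF_R_PLACEHOLDER,
            expected_amplicon_len=518,
            min_len=None,
            max_len=None,
            genetic_code=GeneticCode.STANDARD,
            read_overlap_expected=False,
        ),
    ]


def predict_read_overlap(spec: MarkerSpec, read_len: int, min_overlap: int = 10) -> bool:
    """Will paired reads of ``read_len`` nominally overlap on this marker?

    True iff 2*read_len - sequenced_product_len >= min_overlap. This is the
    geometric prediction; the pipeline itself decides per pair empirically
    (quality truncation can defeat a nominally positive overlap).
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    return 2 * read_len - spec.sequenced_product_len >= min_overlap
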