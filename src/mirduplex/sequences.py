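"""Reference sequences used throughout the package.

Mature miRNA sequences are the published miRBase entries for the miR396
family and the Arabidopsis miR159/miR319 superfamily, typed in as module
constants so the package works fully offline.  Target-site fixtures encode
the canonical duplex architectures of the miR396 regulatory network:

* ``GRF2_SITE`` -- the GROWTH-REGULATING FACTOR class target site.  It is the
  exact reverse complement of ath-miR396a *plus one extra C* opposite the
  miRNA position 7/8 boundary, i.e. the duplex carries a single 1-nt bulge on
  the target strand between miRNA positions 7 and 8 and is otherwise fully
  Watson-Crick paired.
* ``BHLH74_SITE`` -- a bHLH74-class site: the exact reverse complement of
  ath-miR396a with no bulge.  Against the monocot insG variant this site
  leaves the inserted G unpaired, producing a 1-nt bulge on the *miRNA* side.

The monocot-specific variant ``MIR396_78INSG`` (rice miR396e/f) carries a G
inserted between positions 7 and 8 of miR396; it pairs the GRF bulge base and
therefore binds GRF sites more strongly.  ``MIR396B_7AG`` is the point variant
found in Selaginella/pine/poplar lineages, replacing the position-7 A.
"""

from __future__ import annotations

RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, C<->G)."""
    return seq.translate(RNA_COMPLEMENT)[::-1]


# --- miR396 family -----------------------------------------------------------

MIR396A = "UUCCACAGCUUUCUUGAACUG"  # ath-miR396a
MIR396B = "UUCCACAGCUUUCUUGAACUU"  # ath-miR396b

#: monocot-specific variant: G inserted between miR396 positions 7 and 8
MIR396_78INSG = "UUCCACAGGCUUUCUUGAACUG"

#: Selaginella/pine/poplar point variant of miR396b: position 7 A>G
MIR396B_7AG = "UUCCACGGCUUUCUUGAACUU"

# --- target-site fixtures (sense mRNA orientation, 5'->3') ------------------

#: GRF-class site: revcomp(miR396a) with one bulged C between miRNA pos 7/8
GRF2_SITE = "CAGUUCAAGAAAGCCUGUGGAA"

#: bHLH74-class site: bulge-free perfect complement of miR396a
BHLH74_SITE = reverse_complement(MIR396A)

# --- Arabidopsis miR159/miR319 superfamily ----------------------------------

#: The six mature sequences; 5'-anchored they are invariant at 17 of 21
#: positions (variable at positions 1, 7, 20 and 21).
MIR159_MIR319_FAMILY = {
    "ath-miR159a": "UUUGGAUUGAAGGGAGCUCUA",
    "ath-miR159b": "UUUGGAUUGAAGGGAGCUCUU",
    "ath-miR159c": "UUUGGAUUGAAGGGAGCUCUU",
    "ath-miR319a": "CUUGGACUGAAGGGAGCUCCC",
    "ath-miR319b": "CUUGGACUGAAGGGAGCUCCC",
    "ath-miR319c": "CUUGGACUGAAGGGAGCUCCU",
}
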