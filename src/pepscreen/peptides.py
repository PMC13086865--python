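"""Reference Ku80-derived peptide sequences and parent-coordinate anchors.

The four synthesized Ku peptides from the EndoG-inhibitor screen, with
their spans in the absolute numbering of human Ku80.  Two published
spans are internally inconsistent with the sequences and are recorded
here both as printed and as corrected:

* Ku1's span was printed as 586-707, but its 22-residue sequence and
  its 18-residue overlap with Ku3 pin it to 686-707.
* Ku4's span follows from its 30-residue sequence anchored at 607,
  giving 607-636.

``KU1`` is the G-variant actually synthesized (the C-terminal P of the
native 686-707 window replaced by G for synthesis efficiency); the
native window is ``KU1_NATIVE``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferencePeptide:
    name: str
    sequence: str
    parent_start: int       # corrected absolute span (inclusive)
    parent_end: int
    printed_span: tuple[int, int]


KU1 = ReferencePeptide("Ku1", "ITKEEASGSSVTAEEAKKFLAG", 686, 707, (586, 707))
KU1_NATIVE = ReferencePeptide("Ku1-native", "ITKEEASGSSVTAEEAKKFLAP", 686, 707, (586, 707))
KU2 = ReferencePeptide("Ku2", "RVLVKQKKASFEEASNQLINHIEQFL", 599, 624, (599, 624))
KU3 = ReferencePeptide("Ku3", "EIVVQDGITLITKEEASGSSVTAEEAKK", 676, 703, (676, 703))
KU4 = ReferencePeptide("Ku4", "ASFEEASNQLINHIEQFLDTNETPYFMKSI", 607, 636, (607, 635))

REFERENCE_PEPTIDES = {p.name: p for p in (KU1, KU1_NATIVE, KU2, KU3, KU4)}

#: The most conserved heptapeptide among accepted candidates,
#: at absolute residues 687-693 of Ku80.
CONSERVED_MOTIF = "TKEEASG"

#: Ku80-Ct parent region bounds used for library enumeration (120 aa).
PARENT_REGION = (590, 709)
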