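"""Reporter library geometry: constant flanks and insert length model.

A reporter construct carries a variable insert cloned between two constant
flanking sequences in the 3' UTR.  Reads are recognised as valid library
members by exact occurrence of the last/first 10 nt of those flanks (the
"anchors"); the insert is whatever lies strictly between them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ANCHOR_LEN = 10


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def all_kmers(k: int = 6) -> list[str]:
    """All 4^k k-mers over ACGT in lexicographic order."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


@dataclass(frozen=True)
class LibrarySpec:
    """Constant flanks and insert length bounds of a reporter library.

    Parameters
    ----------
    flank5, flank3 :
        Constant sequence upstream / downstream of the insert.  Only the
        last 10 nt of ``flank5`` and the first 10 nt of ``flank3`` are used
        as anchors for read validation.
    insert_len_min, insert_len_max :
        Inclusive bounds on the insert length; both 6 for the saturating
        6-mer library.
    """

    flank5: str
    flank3: str
    insert_len_min: int
    insert_len_max: int

    def __post_init__(self) -> None:
        for name, f in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(f) < ANCHOR_LEN:
                raise ValueError(f"{name} must be at least {ANCHOR_LEN} nt, got {len(f)}")
        if not set(self.anchor5) <= set(ALPHABET):
            raise ValueError("flank5 anchor contains non-ACGT characters")
        if not set(self.anchor3) <= set(ALPHABET):
            raise ValueError("flank3 anchor contains non-ACGT characters")
        if not 0 < self.insert_len_min <= self.insert_len_max:
            raise ValueError(
                f"invalid insert length bounds [{self.insert_len_min}, {self.insert_len_max}]"
            )

    @property
    def anchor5(self) -> str:
        """The 10-nt constant anchor immediately 5' of the insert."""
        return self.flank5[-ANCHOR_LEN:]

    @property
    def anchor3(self) -> str:
        """The 10-nt constant anchor immediately 3' of the insert."""
        return self.flank3[:ANCHOR_LEN]


#: Default 6-mer library geometry.  The flank sequences are synthetic stand-ins
#: for the reporter's 3' UTR context; only their 10-nt anchors matter to the
#: pipeline, and they were chosen not to recreate either anchor internally or
#: across the insert junction.
SIXMER_LIBRARY = LibrarySpec(
    flank5="TCACTAGGAC",
    flank3="GTCCAAGTGA",
    insert_len_min=6,
    insert_len_max=6,
)


def fragment_library_spec(len_min: int = 30, len_max: int = 100) -> LibrarySpec:
    """Library geometry for the random-fragment arm (default 30-100 nt inserts)."""
    return LibrarySpec(
        flank5=SIXMER_LIBRARY.flank5,
        flank3=SIXMER_LIBRARY.flank3,
        insert_len_min=len_min,
        insert_len_max=len_max,
    )
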