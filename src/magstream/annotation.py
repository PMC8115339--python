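"""Annotation decision rules applied to upstream tool outputs.

Three independent rules, each consuming tables produced by standard
annotation tools (PSORTb/SignalP localization calls, dbCAN CAZy family
hits, rhodopsin sequences); the tools themselves are upstream:

* extracellular peptidase calling — localization ``extracellular`` or
  ``cellwall``, or ``unknown`` rescued by a positive signal/membrane
  prediction;
* CAZy per-Mbp rates — subfamily models (``GH13_9``-style) are excluded so
  family and subfamily hits to one protein are not double counted, a
  curated class set (default glycoside hydrolases GH and carbohydrate
  binding modules CBM) is kept, and counts are normalized by assembly
  length;
* rhodopsin function and spectral tuning — read from three diagnostic
  residues in proteorhodopsin reference numbering: the proton
  acceptor/donor pair at sites 97 and 108 (D97 + E108 -> proton pump) and
  the spectral-tuning switch at site 105 (Q -> blue-absorbing, L or M ->
  green-absorbing).

Reference numbering is established by global alignment against a bundled
scaffold sequence, or the caller may supply the pre-aligned 17-residue
window spanning reference positions 94-110.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InputError

LOCALIZATIONS = (
    "extracellular", "cellwall", "unknown", "cytoplasmic", "membrane", "other",
)

CAZY_FAMILY_RE = re.compile(r"^(GH|CBM|GT|PL|CE|AA)([0-9]+)(_[0-9]+)?$")

FUNCTION_SITES = (97, 108)
TUNING_SITE = 105
WINDOW_START, WINDOW_END = 94, 110  # 17-residue diagnostic window

# Synthetic proteorhodopsin-like scaffold, NOT a natural sequence: a
# deterministic stand-in carrying the diagnostic residues D97/L105/E108 at
# the correct reference positions, used for alignment-based site mapping
# and as the template of the synthetic rhodopsin generator.
SYNTHETIC_PR_REFERENCE = (
    ("MGLLFVLSAGTAVMAW" * 6)[:96]       # positions 1-96
    + "D"                               # 97, proton acceptor
    + "AVLGTAY"                         # 98-104
    + "L"                               # 105, spectral tuning switch
    + "IV"                              # 106-107
    + "E"                               # 108, proton donor
    + ("GTLAFVMSAWLIGTAV" * 8)[:120]    # 109-228
)


class RhodopsinFunction(enum.Enum):
    PROTON_PUMP = "proton_pump"
    OTHER = "other/unknown"


class SpectralTuning(enum.Enum):
    BLUE = "blue"
    GREEN = "green"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    localization: str
    signal_predicted: bool

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise InputError(
                f"protein {self.protein_id!r}: unknown localization "
                f"{self.localization!r}"
            )


@dataclass(frozen=True)
class CazyHit:
    protein_id: str
    genome_id: str
    family: str

    def __post_init__(self) -> None:
        if not CAZY_FAMILY_RE.match(self.family):
            raise InputError(
                f"protein {self.protein_id!r}: malformed CAZy family "
                f"{self.family!r}"
            )


@dataclass(frozen=True)
class RhodopsinCall:
    protein_id: str
    residue_97: str
    residue_105: str
    residue_108: str
    function: RhodopsinFunction
    tuning: SpectralTuning


def classify_extracellular(call: LocalizationCall) -> bool:
    """True for extracellular/cellwall localization, or unknown rescued by
    a positive signal prediction."""
    if call.localization in ("extracellular", "cellwall"):
        return True
    return call.localization == "unknown" and call.signal_predicted


def cazy_counts_per_mbp(
    hits: Iterable[CazyHit],
    genome_lengths: Mapping[str, int],
    keep_classes: frozenset[str] | set[str] = frozenset({"GH", "CBM"}),
) -> dict[str, float]:
    """Kept CAZy hits per Mbp for every genome in ``genome_lengths``.

    Subfamily hits (family containing ``_``) are dropped first, then only
    families whose class prefix is in ``keep_classes`` are counted.
    Genomes without hits report 0.0.
    """
    counts: dict[str, int] = {g: 0 for g in genome_lengths}
    for h in hits:
        if h.genome_id not in genome_lengths:
            raise InputError(f"hit for unknown genome {h.genome_id!r}")
        match = CAZY_FAMILY_RE.match(h.family)
        if match.group(3):  # subfamily model, excluded
            continue
        if match.group(1) in keep_classes:
            counts[h.genome_id] += 1
    return {
        g: counts[g] / (genome_lengths[g] / 1e6) for g in genome_lengths
    }


def _site_call(
    protein_id: str, r97: str, r105: str, r108: str
) -> RhodopsinCall:
    if r97 == "D" and r108 == "E":
        function = RhodopsinFunction.PROTON_PUMP
    else:
        function = RhodopsinFunction.OTHER
    if r105 in ("L", "M"):
        tuning = SpectralTuning.GREEN
    elif r105 == "Q":
        tuning = SpectralTuning.BLUE
    else:
        tuning = SpectralTuning.UNKNOWN
    return RhodopsinCall(protein_id, r97, r105, r108, function, tuning)


def classify_rhodopsin_window(window: str, protein_id: str = "") -> RhodopsinCall:
    """Classify from a pre-aligned 17-residue window (positions 94-110)."""
    if len(window) != WINDOW_END - WINDOW_START + 1:
        raise InputError(
            f"window must span positions {WINDOW_START}-{WINDOW_END} "
            f"(17 residues), got {len(window)}"
        )
    w = window.upper()
    return _classify_resolved(
        protein_id, w[97 - WINDOW_START], w[TUNING_SITE - WINDOW_START],
        w[108 - WINDOW_START],
    )


def _classify_resolved(protein_id: str, r97: str, r105: str, r108: str
                       ) -> RhodopsinCall:
    if "-" in (r97, r105, r108):
        warnings.warn(
            f"rhodopsin {protein_id!r}: gap at a diagnostic site "
            f"(97={r97}, 105={r105}, 108={r108}); call is unknown",
            stacklevel=3,
        )
        return RhodopsinCall(
            protein_id, r97, r105, r108,
            RhodopsinFunction.OTHER, SpectralTuning.UNKNOWN,
        )
    return _site_call(protein_id, r97, r105, r108)


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_GLOBAL = _global_aligner()


def map_reference_sites(
    query: str,
    sites: Iterable[int] = (*FUNCTION_SITES, TUNING_SITE),
    reference: str = SYNTHETIC_PR_REFERENCE,
) -> dict[int, str]:
    """Residues of ``query`` at reference positions, via global alignment.

    Returns ``'-'`` for a site aligned to a gap.
    """
    if not query:
        raise InputError("empty query sequence")
    aln = _GLOBAL.align(reference, query.upper())[0]
    indices = aln.indices  # 2 x columns, -1 at gaps
    out: dict[int, str] = {}
    ref_row, qry_row = indices[0], indices[1]
    for site in sites:
        cols = (ref_row == site - 1).nonzero()[0]
        if len(cols) == 0 or qry_row[cols[0]] < 0:
            out[site] = "-"
        else:
            out[site] = query[qry_row[cols[0]]].upper()
    return out


def classify_rhodopsin(
    sequence: str,
    protein_id: str = "",
    reference: str = SYNTHETIC_PR_REFERENCE,
) -> RhodopsinCall:
    """Classify a full-length rhodopsin by aligning it to the reference."""
    sites = map_reference_sites(sequence, reference=reference)
    return _classify_resolved(
        protein_id, sites[97], sites[TUNING_SITE], sites[108]
    )
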