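"""The packaged ornithocheiraean muscle roster.

A transcription of the published MTU table for the 5 m-wingspan
ornithocheiraean musculoskeletal model: 30 pectoral-group rows and 13
pelvic-group rows, each with its code, anatomical name, attachment-area
descriptions, extant-phylogenetic-bracket inference grades for origin and
insertion, and MTU multiplicity (broad muscles carry several lines of
action).  Two pectoral rows (SCM, SC) are flagged as not directly related
to the take-offs.

Attachment-area text is anatomical description only; the packaged model
attaches these rows to synthetic stand-in coordinates (see
``pterolaunch.synthetic``) because the specimen-derived geometry is not
redistributable.  Multiplicities sum to 38 pectoral MTUs (36 take-off
relevant) and 16 pelvic MTUs.
"""

from __future__ import annotations

from typing import List, NamedTuple


class RosterRow(NamedTuple):
    code: str
    name: str
    group: str
    n_lines: int
    take_off_relevant: bool
    origin_inference: str
    insertion_inference: str
    origin_description: str
    insertion_description: str


# fmt: off
TABLE_ROWS: List[RosterRow] = [
    # --- pectoral group ---------------------------------------------------
    RosterRow("SCM", "sternocleidomastoideus", "pectoral", 1, False, "I", "I'",
              "anterior sternum", "squamosal"),
    RosterRow("SC", "sternocoracoideus", "pectoral", 1, False, "II'", "II",
              "anterior margin of sternum", "coracoid"),
    RosterRow("LD", "latissimus dorsi", "pectoral", 3, True, "I'", "I",
              "last cervical neural spine to distal notarium",
              "dorsal (distal) humerus shaft scar"),
    RosterRow("TM", "teres major", "pectoral", 1, True, "II", "II",
              "posterolateral scapula", "dorsal (proximal) humerus shaft scar"),
    RosterRow("DS", "deltoides scapularis", "pectoral", 1, True, "I", "I'",
              "lateral scapula/acromion process",
              "dorsal (anterior) deltopectoral crest"),
    RosterRow("SHA", "scapulohumeralis anterior", "pectoral", 1, True, "II", "II'",
              "scapula anterior to glenoid", "dorsal (proximal) deltopectoral crest"),
    RosterRow("SHP", "scapulohumeralis posterior", "pectoral", 1, True, "I", "I",
              "posterior margin scapula above glenoid",
              "dorsal posterior process of humerus distal to SUBS"),
    RosterRow("SUBS", "subscapularis", "pectoral", 1, True, "I", "I",
              "medial ventral surface scapula", "dorsal posterior process of humerus"),
    RosterRow("TR-S", "triceps", "pectoral", 1, True, "I", "I",
              "scapula - dorsal border of glenoid", "olecranon process ulna"),
    RosterRow("TR-C", "triceps", "pectoral", 1, True, "II'", "II",
              "coracoid - ventral posterior to glenoid", "olecranon process ulna"),
    RosterRow("TR-M", "triceps", "pectoral", 1, True, "I", "I",
              "medial - posterior side humeral shaft", "olecranon process ulna"),
    RosterRow("TR-L", "triceps", "pectoral", 1, True, "II", "II",
              "lateral - anterior side humeral shaft", "olecranon process ulna"),
    RosterRow("PECT", "pectoralis", "pectoral", 4, True, "I", "I",
              "sternum ventral", "entire ventral deltopectoral crest"),
    RosterRow("SUPC", "supracoracoideus", "pectoral", 1, True, "II", "II'",
              "anterior ventral surface of coracoid",
              "ventral proximal to deltopectoral crest"),
    RosterRow("CB", "coracobrachialis", "pectoral", 3, True, "I", "I",
              "posterior ventral coracoid", "ventral posterior to deltopectoral crest"),
    RosterRow("BI", "biceps", "pectoral", 2, True, "I", "I",
              "coracoid biceps tubercule", "proximal radius/ulna"),
    RosterRow("BR", "brachialis", "pectoral", 1, True, "I'", "I",
              "anterior humerus shaft", "proximal radius/ulna"),
    RosterRow("HR", "humeroradialis", "pectoral", 1, True, "II'", "II'",
              "proximal humerus distal to CB", "proximal radius"),
    RosterRow("FDL", "flexor digitorum longus (quarti)", "pectoral", 1, True, "II", "I'",
              "medial epicondyle of humerus and ulna",
              "ventral extensor process WP1 and distal phalanges"),
    RosterRow("FDL-U", "flexor digitorum longus (quarti)", "pectoral", 1, True, "I", "I'",
              "medial ulna shaft", "ventral extensor process WP1 and distal phalanges"),
    RosterRow("EDL", "extensor digitorum longus (quarti)", "pectoral", 1, True, "I", "I'",
              "lateral epicondyle of humerus", "proximal posterior WP1 process"),
    RosterRow("FCU", "flexor carpi ulnaris", "pectoral", 1, True, "I", "II'",
              "medial epicondyle of humerus", "anterior proximal WMC"),
    RosterRow("FCR", "flexor carpi radialis", "pectoral", 1, True, "I", "II",
              "medial epicondyle of humerus", "proximal anterior syncarpal"),
    RosterRow("ECU", "extensor carpi ulnaris", "pectoral", 1, True, "I", "II",
              "lateral epicondyle of humerus", "posterior WMC large scar"),
    RosterRow("ECR", "extensor carpi radialis", "pectoral", 1, True, "I", "II'",
              "lateral epicondyle of humerus", "proximal posterior syncarpal"),
    RosterRow("SUP", "supinator", "pectoral", 1, True, "I", "I",
              "ridge anterior to lateral epicondyle of humerus",
              "3/4 length of posterior radius shaft"),
    RosterRow("PT", "pronator teres", "pectoral", 1, True, "I", "I",
              "medial epicondyle of humerus", "posterior mid shaft"),
    RosterRow("PQ", "pronator quadratus", "pectoral", 1, True, "I", "I",
              "ulna shaft", "posterior distal radius shaft"),
    RosterRow("FDB", "flexor digitorum brevis", "pectoral", 1, True, "II'", "I",
              "dorsal distal syncarpal", "dorsal extensor process WP1"),
    RosterRow("EDB", "extensor digitorum brevis", "pectoral", 1, True, "II'", "II",
              "ventral distal syncarpal", "posterior WP1 process"),
    # --- pelvic group -----------------------------------------------------
    RosterRow("ADD", "adductor femoris", "pelvic", 1, True, "I", "I",
              "lateral surface of the ischium", "medial shaft (diaphysis) of the femur"),
    RosterRow("IFM", "illiofemoralis", "pelvic", 1, True, "I", "I",
              "lateral margin of preacetabular process of the ilium",
              "greater trochanter"),
    RosterRow("PIFE", "puboischiofemoralis externus", "pelvic", 1, True, "I", "I",
              "lateral surface of the pubis", "greater trochanter"),
    RosterRow("PIFI", "puboischiofemoralis internus", "pelvic", 1, True, "I", "I",
              "medial surface of ilium anterior to acetabulum",
              "proximal surface of femur"),
    RosterRow("AMB", "ambiens", "pelvic", 1, True, "I", "I'",
              "pubic tubercule", "cnemial crest of tibia"),
    RosterRow("ITB", "Iliotibialis", "pelvic", 3, True, "I", "I'",
              "lateral margin of preacetabular process of the ilium",
              "cnemial crest of tibia"),
    RosterRow("FTE", "flexor tibialis externus", "pelvic", 1, True, "II", "II'",
              "lateral surface of the postacetabular process of the ilium",
              "medial surface of tibia"),
    RosterRow("FTI-I", "flexor tibialis internus", "pelvic", 2, True, "II", "II'",
              "lateral surface of ischial tuberosity", "posteromedial shaft of tibia"),
    RosterRow("FTI-II", "flexor tibialis internus 2", "pelvic", 1, True, "II", "II'",
              "lateral surface of the postacetabular process of the ilium",
              "posteromedial shaft of tibia"),
    RosterRow("ILF", "iliofibularis", "pelvic", 1, True, "II'", "II'",
              "lateral surface of the postacetabular process of the ilium",
              "posteromedial shaft of tibia"),
    RosterRow("CFB", "caudofemoralis brevis", "pelvic", 1, True, "I'", "I",
              "lateral iliac surface", "posterior (4th) trochanter of femur"),
    RosterRow("FMTE", "femorotibialis externus", "pelvic", 1, True, "I", "I'",
              "proximal femoral shaft", "cnemial crest of tibia"),
    RosterRow("FMTI", "femorotibialis internus", "pelvic", 1, True, "I", "I'",
              "proximal femoral shaft", "cnemial crest of tibia"),
]
# fmt: on


def roster_rows(group: str | None = None) -> List[RosterRow]:
    """The packaged roster rows, optionally filtered by muscle group."""
    if group is None:
        return list(TABLE_ROWS)
    if group not in ("pectoral", "pelvic"):
        raise ValueError(f"unknown muscle group '{group}'")
    return [r for r in TABLE_ROWS if r.group == group]
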