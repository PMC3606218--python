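"""Reported study-scale difference percentages.

The published group comparison reported, for every significant
connection, the absolute patient/control percentage and the relative
percentage (absolute minus the 90% global ratio).  These printed values
serve two purposes here: the lobar rows parameterize the demo cohort's
planted effects, and all rows validate the exact identity
``relative = absolute - global`` that the difference reporting
implements.
"""

from __future__ import annotations

GLOBAL_PCT = 90.0

# (family, connection, absolute %, relative %)
REPORTED_DIFFERENCES: list[tuple[str, str, float, float]] = [
    ("right_hemisphere", "frontal-R:frontal-R", 99.2, 9.2),
    ("right_hemisphere", "parietal-R:occipital-R", 112.9, 22.9),
    ("right_hemisphere", "parietal-R:parietal-R", 93.1, 3.1),
    ("right_hemisphere", "limbic-R:limbic-R", 83.5, -6.5),
    ("left_hemisphere", "frontal-L:temporal-L", 56.1, -33.9),
    ("left_hemisphere", "parietal-L:limbic-L", 79.7, -10.3),
    ("left_hemisphere", "limbic-L:limbic-L", 84.3, -5.7),
    ("left_hemisphere", "occipital-L:occipital-L", 72.0, -18.0),
    ("inter_hemisphere", "limbic-L:limbic-R", 79.4, -10.6),
    ("right_parcel", "rh.paracentral", 116.6, 26.6),
    ("right_parcel", "rh.medialorbitofrontal", 80.7, -9.3),
    ("right_parcel", "rh.rostralanteriorcingulate", 63.3, -26.7),
    ("right_parcel", "rh.lateralorbitofrontal", 112.4, 22.4),
    ("right_parcel", "rh.inferiorparietal", 96.2, 6.2),
    ("right_parcel", "rh.rostralmiddlefrontal", 97.1, 7.1),
    ("right_parcel", "rh.parsorbitalis", 103.7, 13.7),
    ("left_parcel", "lh.posteriorcingulate", 77.2, -12.8),
    ("left_parcel", "lh.cuneus", 73.2, -16.8),
    ("left_parcel", "lh.parahippocampal", 115.6, 25.6),
    ("left_parcel", "lh.middletemporal", 80.0, -10.0),
    ("left_parcel", "lh.precuneus", 75.6, -14.4),
    ("left_parcel", "lh.isthmuscingulate", 82.9, -7.1),
]

LOBAR_ABSOLUTE_PCT: dict[tuple[str, str], float] = {
    tuple(conn.split(":")): abs_pct
    for fam, conn, abs_pct, _ in REPORTED_DIFFERENCES
    if ":" in conn
}

# reported cohort scale: control/patient total-fiber means and spreads
CONTROL_TOTAL_MEAN = 47423.0
CONTROL_TOTAL_SD = 5739.0
PATIENT_TOTAL_MEAN = 43032.0
PATIENT_TOTAL_SD = 4586.0
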