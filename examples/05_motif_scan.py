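"""Scan PROSITE-style PTM patterns and check channel features.

Scans a short receptor-like peptide with the shipped six-pattern PTM
catalog (N-glycosylation, PKC / CK2 / cAMP-cGMP phosphorylation,
N-myristoylation, amidation), then checks channel features: the
cys-loop C-x(13)-C signature and the pore-filter motif in the window
immediately N-terminal of a user-supplied TM2 annotation.
"""

from sitescreen import SeqRecord, check_features, scan
from sitescreen.motifs import read_feature_catalog, read_pattern_catalog

peptide = SeqRecord(
    "toy_receptor",
    # NATA: N-glycosylation site; C-x(13)-C: cys-loop; SSK: PKC site;
    # KDR: pore-filter variant, 3 residues before the TM2 annotation
    "MNATAWDPELKCLLSSKGVRTPWIVC" + "LIVFG" * 6 + "KDRAILVGTTLIVSSAVF",
    alphabet="protein",
)

for pattern in read_pattern_catalog():
    for hit in scan(pattern, peptide):
        print(f"{pattern.name:22s} {hit.matched:8s} at {hit.start}")

# TM2 annotation in 0-based half-open protein coordinates
annotations = {"TM2": (59, 73)}
features = [
    f for f in read_feature_catalog()
    if f.feature_id in ("cys_loop", "pore_filter")
]
for rep in check_features(peptide, annotations, features):
    print(f"{rep.feature_id}: {rep.status}"
          + (f" ({rep.observed} at {rep.position})" if rep.observed else ""))

# Overlapping pattern hits are reported with 1-based starts, the way a
# PTM survey table prints them ("NATA 2"). The pore filter reads KDR -
# a variant of the canonical GEK, as seen in divergent receptor
# subunits - in the 10 residues preceding TM2.
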