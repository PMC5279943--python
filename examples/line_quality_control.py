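"""Line-level QC on the packaged 17-line panel fixture.

Drops reference-blocker (E4031) non-responders and abnormal karyotypes,
leaving the 14-line (7 vs 7) analysis set.
"""

import qtsens as q

lines = q.load_fixture("lines")
qc = q.qc_filter_lines(lines)
kept = qc[qc["retained"]]
print(f"retained {len(kept)}/17 lines "
      f"({(kept['group'] == 'high').sum()} high-S vs {(kept['group'] == 'low').sum()} low-S)")
for _, row in qc[~qc["retained"]].iterrows():
    print(f"excluded {row['line_id']}: {row['exclusion_reason']}")
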