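"""Identify eicosanoid peaks by retention time and [M-H]- m/z.

Builds a small MS peak list around the published anchors and assigns
each peak to its metabolite; same-m/z candidates that cannot be told
apart (HETE positional isomers; PGE2 vs PGD2 without retention-time
evidence) are flagged ambiguous with the alternatives listed.
"""

import corallox as cx

peaks = [
    cx.Peak(17.2, 53.0, "ms", 319.2),   # major LOX product window
    cx.Peak(6.9, 5.0, "ms", 353.2),     # prostaglandin F2a window
    cx.Peak(8.5, 4.0, "ms", 351.2),     # prostaglandin E2 window
    cx.Peak(11.2, 7.0, "ms", 351.2),    # 351.2 away from the PGE2 window
    cx.Peak(12.0, 3.0, "ms", 500.0),    # matches nothing
]

for a in cx.assign_peaks(peaks):
    name = a.metabolite or "unassigned"
    flag = f"  (ambiguous with {', '.join(a.alternatives)})" if a.ambiguous else ""
    print(f"rt {a.peak.rt:5.1f} min  m/z {a.peak.mz:6.1f}  ->  {name}{flag}")

print(
    "\nTolerances: 0.2 min / 0.05 m/z. The HETE isomers share m/z 319.2 and\n"
    "differ only by ~0.2 min, so neighbours inside the window are reported\n"
    "as alternatives; PGD2 has no anchored rt and is never assigned\n"
    "confidently over PGE2 from m/z alone."
)
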