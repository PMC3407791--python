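"""Classify heuristic-evaluation averages into severity bands.

Expert usability inspection rates each of Nielsen's ten principles 0 (no
problem) to 4 (catastrophe). Averages at or above 2.75 are major usability
problems, below 1.5 cosmetic, minor in between. The averages below come
from a published review of a trial pre-screening web tool: error handling
(5), error prevention (6) and documentation (10) were its major problems.
"""

import prescreen as ps

averages = {1: 2.66, 2: 2.66, 3: 2.25, 4: 2.0, 5: 3.0,
            6: 2.75, 7: 1.25, 8: 2.0, 9: 1.0, 10: 3.5}

print(f"{'heuristic':55} {'avg':>5}  severity")
for hid, avg in averages.items():
    severity = ps.classify_severity(avg)
    name = ps.NIELSEN_HEURISTICS[hid]
    print(f"{hid:2}. {name:51} {avg:>5.2f}  {severity.value}")

major = [h for h, a in averages.items() if ps.classify_severity(a) is ps.Severity.MAJOR]
print(f"\nmajor usability problems: heuristics {major} "
      "(fix error prevention and write the manual first)")
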