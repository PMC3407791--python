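"""Terminology lookup with synonym closure.

A brand name and its generic must return the same result set — a search
that answers 'tylenol' and 'acetaminophen' differently silently skews
which medication criteria get authored.
"""

import prescreen as ps

vocab = ps.bundled_vocabulary("drug")

for query in ("tylenol", "acetaminophen"):
    hits = ps.lookup_codes(vocab, query)
    print(f"{query!r} -> {len(hits)} hit(s)")
    for e in hits:
        print(f"  {e.code:8} {e.preferred_name}")

brand = {e.code for e in ps.lookup_codes(vocab, "tylenol")}
generic = {e.code for e in ps.lookup_codes(vocab, "acetaminophen")}
print(f"\nidentical result sets: {brand == generic}")
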