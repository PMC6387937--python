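"""Characterize a designed library: rule of three, shape and sigma-holes."""

import json

from halofrag import (
    FixtureSpec,
    VmaxProvider,
    generate_fixtures,
    profile_library,
)

library = generate_fixtures(FixtureSpec(seed=4, count=30))
profile = profile_library(library, conformer_seed=7, vmax_provider=VmaxProvider())

print("rule of three:", json.dumps(profile.ro3.as_dict(), sort_keys=True))
print(f"mean Fsp3: {profile.shape.fsp3_mean:.3f}  (0 = fully flat/aromatic)")
for element, (lo, q1, med, q3, hi) in profile.vmax.per_element.items():
    ref = profile.vmax.references[element]
    print(
        f"V_max {element}: median {med:.4f} au (quartiles {q1:.4f}-{q3:.4f}, "
        f"halobenzene reference {ref:.3f})"
    )

# Violation counts show how fragment-like the library is; the V_max rows
# show how far each halogen population is tuned above its unsubstituted
# halobenzene sigma-hole.
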