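"""Grade raw particle concentrations into semi-quantitative categories.

Each sediment parameter has fixed concentration cutoffs (particles/µL)
mapping to the ordinal report levels Neg, +1 .. +4.
"""

import urised as u

schemes = u.default_schemes()

samples = [
    ("RBC", 0.4),   # below the +1 bound -> negative
    ("RBC", 10.0),  # inside the +2 band
    ("RBC", 45.55),  # just under the +4 bound -> still +3
    ("bacteria", 150.0),  # above the top bound -> highest level (+3)
    ("sperm", 3.0),  # two-level parameter: any positive is +1
]

print(f"{'parameter':<12} {'conc (p/µL)':>12}  category")
for parameter, conc in samples:
    cat = schemes[parameter].grade(conc)
    print(f"{parameter:<12} {conc:>12}  {u.category_label(cat)}")

print(
    "\nCategories are half-open intervals on the concentration axis, so "
    "every non-negative concentration maps to exactly one report level."
)
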