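"""Estimate live weights with Schaeffer's formula and compare breed means.

Computes W = l * g^2 / 300 (length and heart girth in inches, weight in
pounds) for a few animals, converts to kilograms, then runs the Welch
two-tailed t-test on a conformation parameter between two breeds and
prints the superscript letter groups.
"""

from bsmkit import compare_groups, lbs_to_kg, schaeffer_weight
from bsmkit.pheno import PhenoRecord

animals = [("bull1", 62, 78), ("bull2", 60, 75), ("bull3", 64, 80)]
for name, length, girth in animals:
    w_lbs = schaeffer_weight(length, girth)
    print(f"{name}: l={length}\" g={girth}\" -> {w_lbs:.0f} lbs = {lbs_to_kg(w_lbs):.0f} kg")

records = (
    [PhenoRecord(f"n{i}", "Nili", "male", {"stature": v})
     for i, v in enumerate([52.0, 53.5, 54.0, 52.5])]
    + [PhenoRecord(f"r{i}", "NiliRavi", "male", {"stature": v})
       for i, v in enumerate([50.0, 49.5, 51.0, 50.5])]
)
cmp = compare_groups(records, "stature", ("Nili", "NiliRavi"), variant="welch")
for i in range(2):
    print(f"{cmp.breeds[i]}: {cmp.means[i]:.2f} +/- {cmp.sds[i]:.2f} "
          f"(n={cmp.ns[i]}) ^{cmp.letters[i]}")
print(f"t = {cmp.t:.3f}, df = {cmp.df:.2f}, p = {cmp.p:.4f}")

# Different superscript letters mean the breed means differ at alpha = 0.05
# under the two-tailed Welch test; shared letters mean no detectable
# difference at these sample sizes.
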