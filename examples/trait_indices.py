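"""Compute the leaf trait indices on a small trait table.

PVI scores how far each unit sits from the sample maximum of a trait
(0 = the maximum, 1 = the minimum); LPI sums the four max-normalised
production traits (range (0, 4]); LTI sums the three tolerance traits
(range (0, 3]); their ratio LTI/LPI locates a unit on the
production-tolerance spectrum.
"""

import pandas as pd

from leafspectra import build_index_table, compute_ldmc, compute_sla

# leaf-level measurements -> plot-level traits
print("SLA of a 30 cm^2 leaf weighing 0.1 g dry:", compute_sla(30.0, 0.1), "cm^2/g")
print("LDMC of 0.2 g dry / 1.0 g fresh:", compute_ldmc(0.2, 1.0), "mg/g")

traits = pd.DataFrame(
    {
        "unit_id": ["p1", "p2", "p3", "p4"],
        "leaf_area": [25.0, 40.0, 32.0, 28.0],   # cm^2
        "sla": [120.0, 180.0, 150.0, 135.0],     # cm^2/g
        "ldmc": [310.0, 210.0, 260.0, 290.0],    # mg/g
        "chlorophyll": [30.0, 42.0, 36.0, 33.0], # SPAD
        "leaf_c": [45.0, 40.0, 43.0, 44.0],      # %
        "leaf_n": [1.6, 2.8, 2.2, 1.9],          # %
    }
)

table = build_index_table(traits)  # leaf C:N is derived from leaf C and N
print("\nper-unit indices:")
print(table.round(3).to_string())
# p2 has the largest, thinnest, most N-rich leaves -> highest LPI and the
# lowest spectrum ratio (production end); p1 is dense and C-rich -> the
# tolerance end.
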