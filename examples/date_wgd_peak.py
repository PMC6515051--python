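"""Convert Ks peaks to absolute ages and back with the molecular clock.

T = Ks / (2 r): a peak's synonymous divergence, split over the two
descendant lineages, divided by the synonymous substitution rate per year.
"""

from paleoks import PLANT_AVERAGE_RATE, age_from_ks, rate_from_age

# a WGD peak at Ks ~ 1.13-1.16 under the average plant rate
for ks in (1.13, 1.16):
    res = age_from_ks(ks, PLANT_AVERAGE_RATE)
    print(f"Ks {ks:.2f} at plant rate 6.1e-9 -> {res.age_mya} mya")

# an independently dated peak calibrates a lineage-specific rate ...
derived = rate_from_age(ks=1.148, age_years=52e6)
print(f"\nKs 1.148 dated at 52 Myr -> r = {derived.rate_e9:.2f} x 10^-9 /site/year")

# ... which then dates the same event seen in a sister sample
transferred = age_from_ks(1.199, derived.rate)
print(f"Ks 1.199 at that rate -> {transferred.age_mya} mya")
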