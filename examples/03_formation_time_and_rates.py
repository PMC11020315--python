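"""Tooth formation times and replacement-rate bounds from von Ebner series.

Builds increment-width series matching the three published thin-sections
(one maxillary and two premaxillary teeth), counts daily couplets, and
applies the newly-erupted inference rule: for a just-erupted tooth with no
successor in its family, the formation time bounds the replacement interval
from above.
"""

from zahnreihen import rate_table
from zahnreihen.datasets import jeholosaurus_formation_times
from zahnreihen.simulate import IncrementSimSpec, simulate_increments

published = jeholosaurus_formation_times()
series = []
for i, row in published.iterrows():
    s, _ = simulate_increments(
        IncrementSimSpec(
            n_days=int(row["formation_days"]),
            mean_width=float(row["ddar_um_per_day"]),
            cv=0.08,
            seed=i,
            tooth_id=row["tooth"],
            specimen_id=row["specimen_id"],
            section_plane=row["section_plane"],
        )
    )
    series.append(s)

print(rate_table(series).to_string(index=False))
print()
print("The maxillary tooth (rM8) gives a 46-day replacement-rate bound; the")
print("premaxillary bound rises from 25 days (early juvenile) to 33 days")
print("(subadult) while the daily dentine apposition rate stays similar —")
print("replacement slowed during growth because teeth got bigger, not slower-growing.")
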