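"""Generate a synthetic weekly weather-pest series and discretize it.

Builds a 10-year series, fits a per-feature k=3 interval scheme by 1-D
K-means, and shows how one week's continuous weather becomes a transaction
of interval labels ready for rule mining.
"""

import pestcast as pc

ds = pc.generate_weather_series(n_weeks=520, seed=11)
scheme = pc.fit_scheme(ds, k=3)

print("fitted k=3 interval boundaries (per feature):")
for name, fi in scheme.features.items():
    cuts = ", ".join(f"{c:.2f}" for c in fi.cut_points)
    print(f"  {fi.letter}-{name:4s} cut points [{cuts}]  "
          f"range ({fi.lower:g}, {fi.upper:.2f}]")

week = next(ds.records())
transaction = pc.discretize_record(week, scheme)
print(f"\nweek 0: MaxT={week.max_t:.1f} MinT={week.min_t:.1f} "
      f"RH1={week.rh1:.1f} RH2={week.rh2:.1f} RF={week.rf:.1f} "
      f"WS={week.ws:.1f} SSH={week.ssh:.1f} EVP={week.evp:.1f}")
print("discretized transaction:", sorted(transaction))
print("\nEach label <letter><i> is the i-th (lowest to highest) interval of "
      "that feature;\nthe item P would mark pest occurrence.")
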