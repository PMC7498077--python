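"""Fit a parameter database from a field-measurement table.

Measurement tables are long-format CSVs (plant_id, organ_class, instance_id,
parameter, value, units).  Each (organ, parameter) sample is tested for
normality (Shapiro-Wilk at alpha = 0.05): parameters that look normal are
stored as normal laws, the rest as piecewise-uniform empirical laws; organ
counts become discrete frequency tables.
"""

from tuberoot import build_database, default_truth, generate_measurements

cfg = default_truth(1, n_plants=50, seed=0)
table = generate_measurements(cfg)
print(f"campaign table: {len(table)} rows, "
      f"{table['plant_id'].nunique()} plants")

db = build_database(table, variety="Zaodabai")
for organ in ("creeping_root",):
    print(f"\nfitted specs for {organ}:")
    for name, spec in db.organs[organ].items():
        if spec.kind == "normal":
            print(f"  {name:22s} normal(mu={spec.mu:.2f}, "
                  f"sigma={spec.sigma:.2f})")
        else:
            print(f"  {name:22s} empirical, {len(spec.intervals)} intervals, "
                  f"mean {spec.mean():.2f}")

truth = cfg.database.spec("creeping_root", "axial_angle_deg")
fitted = db.spec("creeping_root", "axial_angle_deg")
print("\naxial-angle interval probabilities, truth vs refit:")
for (a, b), p in zip(truth.intervals, truth.probs):
    print(f"  [{a:3.0f}, {b:3.0f}]  {p:.2f}  {fitted.interval_prob(a, b):.3f}")
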