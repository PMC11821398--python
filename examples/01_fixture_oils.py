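"""Build the synthetic study data: pure-oil tables and mixed samples.

Generates ground-truth Gaussians for cactus seed oil (CO) and sunflower
oil (SO) from published composition ranges, emulates the measured
dataset (27 CO and 10 SO samples, 33 physically-mixed validation
samples), and validates the tables.
"""

import numpy as np

from oilauth import make_fixture_bundle, validate_table

bundle = make_fixture_bundle()
schema = bundle.schema

print(f"schema: {schema.n_features} features "
      f"({len(schema.features_in_block('FA'))} FA, "
      f"{len(schema.features_in_block('TAG'))} TAG, "
      f"{len(schema.features_in_block('TOCO'))} tocochromanols)")

for name, table in [("observed CO", bundle.observed_co),
                    ("observed SO", bundle.observed_so),
                    ("real-world mixtures", bundle.real_world_mixtures)]:
    report = validate_table(table)
    print(f"{name}: {len(table)} samples, validation "
          f"{'passed' if report.passed else report.issues}")

# The two oils differ most in their tocopherol profile: gamma-tocopherol
# dominates CO while alpha-tocopherol dominates SO.
for feat in ("linoleic", "oleic", "alpha_tocopherol", "gamma_tocopherol"):
    i = schema.index_of(feat)
    co_mean = bundle.observed_co.matrix()[:, i].mean()
    so_mean = bundle.observed_so.matrix()[:, i].mean()
    print(f"{feat:>18}: CO {co_mean:6.2f} %   SO {so_mean:6.2f} %")
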