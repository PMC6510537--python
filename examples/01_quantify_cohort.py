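"""Simulate a TIF cohort, calibrate, and quantify by both paths.

Builds a synthetic study (149-metabolite library, 25 TIF samples with strong
per-sample matrix effects), quantifies the internal standards from the pool
dilution series, converts cohort peak areas into absolute concentrations, and
compares both quantification paths against the known ground truth.
"""

import numpy as np

from tifquant import calibration, quantify
from tifquant.synthetic import (
    GroundTruthConfig,
    GroupSpec,
    MatrixFactorSpec,
    SyntheticStudy,
)

config = GroundTruthConfig(
    groups=(GroupSpec("tif", 25, matrix_type="tif"),),
    matrix_factors={
        "water": MatrixFactorSpec(kind="fixed", value=1.0),
        "standard_dilution": MatrixFactorSpec(kind="fixed", value=1.0),
        "tif": MatrixFactorSpec(kind="uniform", low=0.3, high=3.0),
        "plasma": MatrixFactorSpec(kind="lognormal", geometric_sd=1.6),
    },
    seed=1,
)
study = SyntheticStudy(config)
truth, sheet, peaks = study.generate_cohort()
dilutions, dilution_sheet = study.generate_standard_dilutions()

model = calibration.build_calibration_model(dilutions, study.library, dilution_sheet)
print(f"library: {len(study.library)} metabolites in {len(study.library.pool_ids)} pools")
print(f"internal standards quantified: {len(model.is_quants)}")
print(f"external curves fitted: {len(model.curves)} "
      f"({sum(not c.passes_qc for c in model.curves.values())} failed the r² gate)")

table = quantify.assemble_concentration_table(
    [
        quantify.quantify_isotope_dilution(peaks, model, study.library),
        quantify.quantify_external(peaks, model, study.library),
    ],
    sample_sheet=sheet,
    group_factor="group",
)
print("cell statuses:", table.status_counts().to_dict())

wide, statuses = table.wide(), table.statuses()
truth_vals = truth.concentrations.loc[wide.index, wide.columns]
rel = ((wide - truth_vals) / truth_vals).abs()
for path, status in (
    ("isotope dilution", "quantified_isotope_dilution"),
    ("external calibration", "quantified_external"),
):
    err = rel.where(statuses == status).stack()
    print(f"{path}: median |relative error| = {err.median():.1%} over {len(err)} cells")

# Despite matrix factors spanning 0.3-3x, isotope dilution stays accurate
# (the factor cancels in the labeled/unlabeled ratio); external calibration
# inherits the per-sample matrix bias and is only semi-quantitative.
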