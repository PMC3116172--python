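"""Build the ranked SAR suggestion table for the signal cell line using a
binary Bayes model trained on the whole labeled library."""

import numpy as np

from cycloqsar.chem_io import CYCLOPAMINE_IC50
from cycloqsar.descriptors import build_matrix
from cycloqsar.models import binarize, fit_binary_bayes
from cycloqsar.sar import build_sar_report
from cycloqsar.synth import DEFAULT_SCAFFOLDS, GeneratorConfig, generate_library

CELL = "NCI-H446"

library, _ = generate_library(GeneratorConfig(seed=0))
raw = build_matrix(library, "general")
labels = binarize(library, CELL, CYCLOPAMINE_IC50[CELL])
model = fit_binary_bayes(raw.values, np.asarray(labels.labels))

report = build_sar_report(
    model, library, DEFAULT_SCAFFOLDS, top_n=10, descriptor_names=raw.names
)
print(f"mean input P(active) = {report.mean_input_probability:.3f}")
cols = ["rank", "parent", "scaffold", "mutation", "percent_gain", "weight", "smiles"]
print(report.table[cols].round(3).to_string(index=False))
report.to_csv("results/sar_suggestions.csv")
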