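"""Generate the default synthetic 93-compound library and export it as a
fixture (structures, activities, ground truth, config echo)."""

from pathlib import Path

from cycloqsar.synth import GeneratorConfig, export_fixture, generate_library

OUT = Path("results/fixture")

config = GeneratorConfig(seed=0)
library, truth = generate_library(config)
paths = export_fixture(library, truth, OUT, config)

print(f"{len(library)} compounds -> {OUT}")
n_scaffold = sum(1 for sid, _ in truth.assignments.values() if sid)
print(f"scaffolded: {n_scaffold}, off-scaffold: {len(library) - n_scaffold}")
for cl in library.cell_lines:
    active = truth.labels[cl].mean()
    print(f"  {cl:>9}: noiseless active fraction {active:.3f}")
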