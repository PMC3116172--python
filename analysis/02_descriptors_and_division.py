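"""Compute both descriptor sets for the default library and write the two
dataset divisions (diverse and cluster + diverse) to results/."""

from pathlib import Path

from cycloqsar.descriptors import build_matrix, normalize
from cycloqsar.division import cluster_diverse_split, rank_diverse, split_by_rank
from cycloqsar.synth import GeneratorConfig, generate_library

OUT = Path("results")
OUT.mkdir(exist_ok=True)

library, _ = generate_library(GeneratorConfig(seed=0))

for tag, fname in (("general", "descriptors_general.csv"),
                   ("drug_like_index", "descriptors_drug_like.csv")):
    raw = build_matrix(library, tag)
    df = raw.to_frame()
    df.index.name = "id"
    df.to_csv(OUT / fname, float_format="%.6g")
    norm, info = normalize(raw)
    print(f"{tag}: {len(raw.names)} columns, {len(info.dropped)} constant dropped")

    split = split_by_rank(rank_diverse(norm), 0.65)
    split.to_csv(OUT / f"split_diverse_{tag}.csv", library.ids)
    csplit, clustering = cluster_diverse_split(norm, seed=0)
    csplit.to_csv(OUT / f"split_cluster_diverse_{tag}.csv", library.ids, clustering)
    print(
        f"  diverse {len(split.train_indices)}/{len(split.test_indices)}, "
        f"cluster-diverse {len(csplit.train_indices)}/{len(csplit.test_indices)} "
        f"({clustering.n_clusters} clusters)"
    )
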