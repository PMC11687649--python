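"""Visualize combined HCs vs the healthy core vs patients with t-SNE.

Mirrors the qualitative check that combined HCs show mixed, noisy
patterns while the selected core forms a compact cluster against
patients.  Writes a PNG next to this script's working directory.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from healthycore import (
    CoreConfig,
    SyntheticConfig,
    embed_diagnostic,
    generate_two_site_study,
    select_healthy_core,
    split_by,
)

study = generate_two_site_study(SyntheticConfig(seed=2))
hc_1 = split_by(study.tables["DS1"], "group")["HC"]
hc_2 = split_by(study.tables["DS2"], "group")["HC"]
cm_1 = split_by(study.tables["DS1"], "group")["CM"]
core = select_healthy_core(
    hc_1, hc_2,
    CoreConfig(stop_rule="target_size",
               target_size=len(study.core_subject_ids()), seed=2),
)
core_ids = core.core_ids()

labels = (
    ["HC (combined)"] * (hc_1.n_subjects + hc_2.n_subjects)
    + ["CM"] * cm_1.n_subjects
)
coords = embed_diagnostic([hc_1, hc_2, cm_1], labels=labels, seed=0)
coords["in_core"] = coords["subject_id"].isin(core_ids)

fig, ax = plt.subplots(figsize=(6, 5))
for label, marker in (("HC (combined)", "o"), ("CM", "s")):
    sub = coords[coords["label"] == label]
    ax.scatter(sub["x"], sub["y"], label=label, marker=marker, alpha=0.5)
sub = coords[coords["in_core"]]
ax.scatter(sub["x"], sub["y"], label="healthy core", marker="*", s=120,
           edgecolor="k")
ax.legend()
ax.set_title("t-SNE: combined HCs, healthy core, chronic migraine")
fig.savefig("tsne_diagnostic.png", dpi=120)
print(f"embedded {len(coords)} subjects; core members: {int(coords['in_core'].sum())}")
print("wrote tsne_diagnostic.png")
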