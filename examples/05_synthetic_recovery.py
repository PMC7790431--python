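"""Latent-structure recovery harness.

Each synthetic world hides a development order z and a disease complexity
order w.  The report runs the full pipeline on replicate worlds and measures
how well the indices recover the hidden orderings — and how faithfully the
RDD binarization reproduces the planted incidence pattern (it cannot do so
perfectly: RDD measures relative specialization, and every country's
world-share-weighted mean RDD is identically 1).
"""

from healthspace import recovery_report

rep = recovery_report(l=60, k=120, noise=0.05, n_seeds=10, seed=1)
for key, value in rep.items():
    if key != "n_seeds":
        print(f"{key:>22s}: {value:+.3f}")
print(f"{'replicates':>22s}: {rep['n_seeds']}")
print(
    "-> Spearman rows measure ordering recovery; cell_agreement is the\n"
    "   fraction of incidence cells where binarized RDD matches the planted\n"
    "   pattern (structurally capped well below 1, see docs/methods.md)."
)
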