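"""Health and Disease Complexity Indices (HCI / DCI).

Both indices are the standardized eigenvector of the second-largest
eigenvalue of a row-stochastic similarity matrix built from a binary
country-disease incidence matrix; the country side ranks countries, the
disease side ranks diseases.

Two routes are shown: (a) indices computed from the planted incidence
pattern itself, which demonstrates that the spectral method recovers the
hidden orderings almost perfectly; (b) the full pipeline through the RDD
ratio of prevalence shares, whose binarization is a genuinely different —
relative, not absolute — view of the same world.
"""

from scipy.stats import spearmanr

from healthspace import (
    IncidenceMatrix,
    binarize,
    complexity_from_incidence,
    compute_rdd,
    generate_world,
)

world = generate_world(l=40, k=60, noise=0.05, seed=3)

# (a) spectral indices on the planted incidence pattern
M_true = IncidenceMatrix(world.M_true, world.countries, world.diseases)
hci = complexity_from_incidence(M_true, side="countries")
dci = complexity_from_incidence(M_true, side="diseases")
print("indices on the planted incidence pattern:")
print(f"  HCI mean {hci.values.mean():+.2e}, sd {hci.values.std():.6f}; "
      f"second eigenvalue {hci.second_eigenvalue:.4f}, eigengap {hci.eigengap:.4f}")
print(f"  Spearman(HCI, latent development): "
      f"{spearmanr(hci.values, world.z).statistic:.3f}")
print(f"  Spearman(DCI, latent complexity):  "
      f"{spearmanr(dci.values, world.w).statistic:.3f}")

# (b) full pipeline: prevalence -> RDD -> binarize -> indices
M = binarize(compute_rdd(world.to_matrix()))
hci_rdd = complexity_from_incidence(M, side="countries")
dci_rdd = complexity_from_incidence(M, side="diseases")
print("indices through the RDD pipeline on prevalence rates:")
print(f"  Spearman(HCI, latent development): "
      f"{spearmanr(hci_rdd.values, world.z).statistic:.3f}")
print(f"  Spearman(DCI, latent complexity):  "
      f"{spearmanr(dci_rdd.values, world.w).statistic:.3f}")
print(
    "-> the spectral method itself recovers the hidden orderings; the RDD\n"
    "   stage measures relative specialization, so its binary pattern is a\n"
    "   different object from the planted one (see docs/methods.md)."
)
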