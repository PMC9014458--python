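"""Ground-truth recovery on the synthetic toy dianion.

Samples a 298 K rigid-water ensemble around the symmetric two-site toy
dianion, clusters it, weights the representatives by cluster
population, attaches site-additive detachment energies, and compares
the recovered ensemble-mean VDE with the analytic ground truth (both
basins equally populated by symmetry).
"""

import numpy as np

from microsolv.clustering import cluster_daura, rmsd_matrix, select_representatives
from microsolv.constants import R_KCAL
from microsolv.synthetic import (
    ObservableModel,
    ToyModelParams,
    assign_synthetic_observables,
    build_toy_solute,
    sample_configurations,
)
from microsolv.thermo import equilibrium_fractions, weighted_observable

params = ToyModelParams(seed=5, mc_steps=20000, n_waters=1, stride=100, equilibration=2000)
solute = build_toy_solute(params)
ensemble = sample_configurations(solute, params)
assignment = cluster_daura(rmsd_matrix(ensemble), cutoff=1.0)
reps = select_representatives(assignment, ensemble)

sizes = sorted(assignment.cluster_sizes, reverse=True)
delta_g = [-R_KCAL * params.temperature * np.log(s / sizes[0]) for s in sizes]
x = equilibrium_fractions(delta_g, params.temperature)

model = ObservableModel(noise_sd=0.0)
records = assign_synthetic_observables(reps, model, angle_min=120.0)
recovered = weighted_observable([r.vde for r in records], x)
truth = model.vde0 + 0.5 * sum(model.site_increments.values())

print(f"frames sampled        : {len(ensemble)}")
print(f"clusters found        : {assignment.n_clusters} (sizes {sizes})")
print(f"recovered <VDE>       : {recovered:.4f} eV")
print(f"analytic ground truth : {truth:.4f} eV")
print(f"absolute error        : {abs(recovered - truth):.4f} eV")
print()
print("A small error shows the clustering + Boltzmann-weighting stages")
print("reproduce the sampler's basin populations without bias.")
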