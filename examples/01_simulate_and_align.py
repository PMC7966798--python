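"""Generate a synthetic two-population landmark study and superimpose it.

Builds 120 stylized faces (2 populations x 30 per sex) with a known
sex-difference vector, writes them as TPS + CSV, reads them back, and runs
the full superimposition stack: GPA, bending-energy semilandmark sliding,
and bilateral symmetrization.
"""

import tempfile
from pathlib import Path

import numpy as np

import dimorph as dm

spec = dm.default_spec(seed=0, n_populations=2, n_per_sex=30)
dataset = dm.generate_dataset(spec)

with tempfile.TemporaryDirectory() as tmp:
    paths = dataset.write(Path(tmp))
    configs = dm.read_tps(paths["tps"])
    metadata = dm.read_metadata(paths["metadata"])
    template = dm.read_template(paths["template"])

raw = dm.assemble_dataset(configs, metadata, template)
print(f"assembled {len(raw)} faces; counts per population x sex:")
print(raw.counts.to_string(index=False))

aligned = dm.gpa(raw)
print(f"\nGPA converged in {aligned.gpa_iterations} iterations")

slid = dm.slide_semilandmarks(aligned)
h = slid.energy_history
print(f"sliding reduced total bending energy {h[0]:.3f} -> {h[-1]:.3f}")

sym = dm.symmetrize(slid)
print(f"symmetrized: provenance = {sym.provenance()}")
print("\nEach face is now a unit-size shape vector in a common frame;")
print("the energy drop shows semilandmarks relaxing along the face outline.")
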