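"""Generate a small synthetic phantom dataset and describe its contents.

Each subject is a 64^3 brain-like volume with quasi-spherical microbleeds
(2-10 mm, hypointense on SWI), tubular vessel mimics, boundary-adjacent blob
mimics and Gaussian noise, plus a brain mask and a CMB ground-truth map.
"""

import tempfile
from pathlib import Path

from cmbkit.phantom import PhantomSpec, generate_dataset

outdir = Path(tempfile.mkdtemp(prefix="cmb_phantoms_"))
spec = PhantomSpec(modality="SWI")
manifest = generate_dataset(spec, n_subjects=3, seed=42, outdir=outdir)

print(f"wrote {manifest['n_subjects']} subjects to {outdir}")
for sub in manifest["subjects"]:
    counts = sub["object_counts"]
    cmbs = [o for o in sub["objects"] if o["type"] == "cmb"]
    sizes = ", ".join(f"{o['diameter_mm']:.1f}" for o in cmbs)
    print(
        f"  {sub['id']}: {counts.get('cmb', 0)} CMBs (diameters {sizes} mm), "
        f"{counts.get('vessel', 0)} vessels, "
        f"{counts.get('boundary_mimic', 0)} boundary mimics"
    )
# The ground-truth maps drive training; the vessels and boundary mimics are
# the false-positive sources the later pipeline stages are meant to reject.
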