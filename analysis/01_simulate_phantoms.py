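#!/usr/bin/env python
"""Generate one example scene per phantom family and save it under
results/phantoms/ (volumes as OME-TIFF, ground truth as JSON).

These are the same generators the downstream analyses draw from; this
script exists to make the raw synthetic inputs inspectable in Fiji or
napari.
"""
import json
from pathlib import Path

import numpy as np

from retinaquant import synthgen as sg, volio
from retinaquant.cli import _json_default
from retinaquant.studies import _tuft_scene, _vessel_scene

OUT = Path("results/phantoms")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 42

# 1. plexus with one measurable tube, plus its flat-mounted counterpart
spec, _ = _vessel_scene(radius_um=8.0, seed=SEED)
vol, truth = sg.make_plexus_volume(spec)
volio.write_volume(OUT / "plexus_lsfm.ome.tif", vol)
vol_c, truth_c = sg.apply_flatmount_distortion(vol, truth, 0.4, unbend=True)
volio.write_volume(OUT / "plexus_flatmount.ome.tif", vol_c)

# 2. one medium tuft with a tunnel
tuft = sg.TuftSpec((60.0, 60.0), n_nuclei=12, n_connections=3, n_tunnels=1,
                   curved_nuclei_fraction=0.5, target_volume_um3=3.3e4,
                   protrusion_height_um=45.0)
vol_t, truth_t = sg.make_tuft_volume(_tuft_scene(tuft, seed=SEED))
volio.write_volume(OUT / "tuft_medium.ome.tif", vol_t)

# 3. short rendered time lapse + its track table
rng = np.random.default_rng(SEED)
filo = sg.filopodia_cohort("p5", rng, n=3)
bundles = sg.bundle_cohort(rng, n=2)
vol_4d, tracks, truth_k = sg.make_timelapse(filo, bundles, volume_shape=(32, 64, 64),
                                            seed=SEED)
volio.write_volume(OUT / "timelapse.ome.tif", vol_4d)
tracks.to_csv(OUT / "timelapse_tracks.csv", index=False)

# 4. layered ONL-like slab
vol_l, truth_l = sg.make_layered_volume(5e-3, 60.0, seed=SEED)
volio.write_volume(OUT / "onl_slab.ome.tif", vol_l)

truths = {
    "plexus": truth.to_json_dict(),
    "plexus_flatmount": truth_c.to_json_dict(),
    "tuft": truth_t.to_json_dict(),
    "timelapse": truth_k.to_json_dict(),
    "layers": truth_l.to_json_dict(),
}
(OUT / "ground_truth.json").write_text(json.dumps(truths, default=_json_default, indent=2))
print(f"wrote phantom family examples to {OUT}/")
print(f"  tuft realized volume: {truth_t.tufts[0]['realized_volume_um3']:.0f} µm³, "
      f"{truth_t.tufts[0]['n_nuclei']} nuclei, {truth_t.tufts[0]['n_tunnels']} tunnel(s)")
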