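#!/usr/bin/env python
"""Render the phantom suite: one mitochondrion per crista shape class plus a
width-study mitochondrion, writing MRC volumes, label volumes and ground
truth under results/phantoms/.  Everything downstream is measured on these
fully known synthetic tomograms."""

import os

import cristoscope.phantom as ph
from cristoscope.volio import Tomogram, write_labels, write_volume

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "phantoms")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    for name, crista in ph.exemplar_cristae().items():
        spec = ph.exemplar_phantom(crista, seed=5)
        tomo, labels, ground = ph.generate_phantom(spec)
        write_volume(tomo, os.path.join(OUT, f"{name}.mrc"))
        write_labels(labels, spec.voxel_size_nm, os.path.join(OUT, f"{name}_labels.mrc"))
        ground.save(os.path.join(OUT, name))
        print(
            f"{name:15s} box {tomo.shape}, crista width {crista.width_nm:.0f} nm, "
            f"compartments (um^3): matrix {ground.volumes_um3['matrix_um3']:.4f}, "
            f"IMS {ground.volumes_um3['ims_um3']:.4f}, CL {ground.volumes_um3['cl_um3']:.5f}"
        )
    print(f"phantoms written to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
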