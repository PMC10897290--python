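"""Compartment label map shared by the phantom generator and 3-D morphometry.

The label volume marks, per voxel, which mitochondrial compartment the voxel
belongs to: the two membranes (outer membrane and inner boundary membrane),
the intermembrane space between them, the matrix, and — inside the matrix —
crista membranes and the cristae lumen they enclose.
"""

from enum import IntEnum


class Compartment(IntEnum):
    BACKGROUND = 0
    OMM = 1            # outer mitochondrial membrane
    IMS = 2            # intermembrane space (OMM <-> IBM)
    IBM = 3            # inner boundary membrane
    MATRIX = 4
    CRISTA_MEMBRANE = 5
    CRISTA_LUMEN = 6


MEMBRANE_LABELS = (Compartment.OMM, Compartment.IBM, Compartment.CRISTA_MEMBRANE)

#: compartments whose volumes sum to the total enclosed volume
VOLUME_COMPARTMENTS = (Compartment.MATRIX, Compartment.IMS, Compartment.CRISTA_LUMEN)
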