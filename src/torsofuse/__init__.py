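"""torsofuse: multimodal registration of the scoliotic torso.

Fuses prone-position axial MRI slices, standing-position biplanar
X-ray spine reconstructions and standing-position surface topography
into one 3D patient model: an articulated spine model aligns the bone,
a rigidity-constrained weighted thin-plate spline confines the soft
tissue to the trunk surface, and the result is validated with 2D/3D
Dice overlap and Jacobian-determinant maps.
"""

__version__ = "0.1.0"

from . import articulated, geometry, imagedata, phantom, soft_tissue, tps, validation

__all__ = [
    "articulated",
    "geometry",
    "imagedata",
    "io",
    "phantom",
    "pipeline",
    "soft_tissue",
    "tps",
    "validation",
]


def __getattr__(name):
    # io/pipeline/cli import heavier deps (nibabel, click); load lazily.
    if name in ("io", "pipeline", "cli"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
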