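import numpy as np
import pytest

from dentmorph.outlines import Outline2D, normalize_configuration, radial_pseudolandmarks
from dentmorph.shapespace import fit_shape_pca
from dentmorph.synthetic import (VoxelCrownSpec, generate_outline_population,
                                 generate_voxel_crown, two_group_specs)


def circle_outline(radius: float = 1.0, n: int = 720, center=(0.0, 0.0)) -> Outline2D:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline2D(np.column_stack([center[0] + radius * np.cos(th),
                                      center[1] + radius * np.sin(th)]))


def ellipse_outline(a: float, b: float, n: int = 2000) -> Outline2D:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline2D(np.column_stack([a * np.cos(th), b * np.sin(th)]))


@pytest.fixture(scope="session")
def separable_population():
    """Two-group outline population at the ~0.95 Bayes-accuracy separation."""
    specs = two_group_specs(separation_sigma=3.29)
    pop = generate_outline_population(list(specs), [60, 60], sampling_points=256, seed=11)
    return pop


@pytest.fixture(scope="session")
def separable_scores(separable_population):
    """(scores on selected PCs, labels, model) for the separable population."""
    from dentmorph.shapespace import select_pcs

    cfgs = [normalize_configuration(radial_pseudolandmarks(o))
            for o in separable_population.outlines]
    model = fit_shape_pca(cfgs, separable_population.labels)
    k = select_pcs(model, 0.92)
    return model.training_scores[:, :k], np.array(separable_population.labels), model


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Dentine cylinder r=2 mm, h=4 mm with a 1 mm enamel shell, 0.05 mm voxels."""
    return generate_voxel_crown(VoxelCrownSpec(
        dentine_outline=circle_outline(2.0, n=256), dentine_height=4.0,
        enamel_thickness=1.0, voxel_size=0.05))


def cylinder_shell_analytics(r: float = 2.0, R: float = 3.0, h: float = 4.0) -> dict:
    """Closed forms for the lateral slab of the concentric-cylinder phantom."""
    ve = np.pi * h * (R ** 2 - r ** 2)
    sedj = 2.0 * np.pi * r * h
    ldpv = np.pi * r ** 2 * h
    laet = ve / sedj  # == (R^2 - r^2) / (2 r)
    return {"Ve": ve, "SEDJ": sedj, "LDPV": ldpv, "LAET": laet,
            "LRET": laet / ldpv ** (1.0 / 3.0)}
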