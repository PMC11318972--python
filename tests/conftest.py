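import numpy as np
import pytest

from arbornet.trace_io import ArborTrace, HairCell, HairCellCluster, SkeletonPath


def line_path(pid, p0, p1, n=5, **kw):
    pts = np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)
    return SkeletonPath(path_id=pid, points=pts, **kw)


@pytest.fixture
def straight_trace():
    return ArborTrace(paths=[line_path("p0", (0, 0, 0), (10, 0, 0))])


@pytest.fixture
def y_trace():
    """Y-shaped trace: stem plus two branches sharing the fork point."""
    stem = line_path("p0", (0, 0, 0), (5, 0, 0))
    b1 = line_path("p1", (5, 0, 0), (10, 3, 0), parent_id="p0")
    b2 = line_path("p2", (5, 0, 0), (10, -3, 0), parent_id="p0")
    return ArborTrace(paths=[stem, b1, b2])


@pytest.fixture
def triangle_trace():
    """Triangle with side lengths 3, 4, 5 between corners A, B, C."""
    A = (0.0, 0.0, 0.0)
    B = (3.0, 0.0, 0.0)
    C = (0.0, 4.0, 0.0)
    # stubs make the corners junctions so they survive degree-2 collapse
    return ArborTrace(
        paths=[
            line_path("e_ab", A, B),
            line_path("e_ac", A, C),
            line_path("e_bc", B, C),
            line_path("s_a", A, (-2.0, -2.0, 0.0)),
            line_path("s_b", B, (5.0, -2.0, 0.0)),
            line_path("s_c", C, (-2.0, 6.0, 0.0)),
        ]
    )


@pytest.fixture
def sphere_cluster():
    """A single spherical 'cell' of radius 10 centered at the origin."""
    return HairCellCluster(
        apex_center=np.array([0.0, 0.0, 10.0]),
        base_point=np.array([0.0, 0.0, -10.0]),
        cells=[HairCell(center=np.zeros(3), semi_axes=np.full(3, 10.0), polarity="rostral")],
    )


def circle_points(n=200, radius=1.0, closed=True, plane="xy"):
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    if closed:
        th = np.concatenate([th, th[:1] + 2 * np.pi])
    x = radius * np.cos(th)
    y = radius * np.sin(th)
    z = np.zeros_like(x)
    if plane == "xy":
        return np.stack([x, y, z], axis=1)
    return np.stack([x, z, y], axis=1)
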