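"""Derivation of the frozen tetrad-placement constants.

Places the idealized planar guanine base (standard reference-frame
geometry) at four-fold rotations about the channel axis and solves for
the in-plane base rotation PHI, the C1' azimuth ALPHA and the C1' radius
R such that both Hoogsteen heavy-atom donor-acceptor distances,
N1(i)-O6(i+1) and N2(i)-N7(i+1), equal 2.9 Å exactly.  The solution is
frozen as TETRAD_PHI / TETRAD_ALPHA / DEFAULT_C1_RADIUS in
``g4integrity.synthetic``; run this script to re-derive and verify them.

Usage:  python scripts/derive_tetrad_calibration.py
"""

import numpy as np
from scipy.optimize import least_squares

from g4integrity.templates import BASE_FRAME
from g4integrity import synthetic

TARGET = 2.9  # Å


def place(phi: float, alpha: float, radius: float) -> dict[str, np.ndarray]:
    frame = BASE_FRAME["DG"]
    names = list(frame)
    pts = np.array([frame[n] for n in names])
    c1 = np.array(frame["C1'"])
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    placed = (pts - c1) @ rot.T + radius * np.array([np.cos(alpha), np.sin(alpha)])
    return dict(zip(names, placed))


def hoogsteen_distances(x: np.ndarray) -> np.ndarray:
    donor = place(*x)
    rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])  # neighbour, +90 deg CCW
    acceptor = {n: rot90 @ p for n, p in donor.items()}
    return np.array([
        np.linalg.norm(donor["N1"] - acceptor["O6"]),
        np.linalg.norm(donor["N2"] - acceptor["N7"]),
    ])


def main() -> None:
    best = None
    for phi0 in np.linspace(0.0, 2.0 * np.pi, 25):
        for alpha0 in np.linspace(0.0, 2.0 * np.pi, 25):
            fit = least_squares(
                lambda x: hoogsteen_distances(x) - TARGET,
                [phi0, alpha0, 8.2],
                bounds=([0.0, 0.0, 6.0], [2.0 * np.pi, 2.0 * np.pi, 10.0]))
            if best is None or fit.cost < best.cost:
                best = fit
    phi, alpha, radius = best.x
    d = hoogsteen_distances(best.x)
    print(f"TETRAD_PHI         = {phi!r}")
    print(f"TETRAD_ALPHA       = {alpha!r}")
    print(f"DEFAULT_C1_RADIUS  = {radius!r}")
    print(f"Hoogsteen N1-O6    = {d[0]:.6f} Å")
    print(f"Hoogsteen N2-N7    = {d[1]:.6f} Å")
    print(f"O6 channel radius  = "
          f"{np.linalg.norm(place(*best.x)['O6']):.3f} Å")
    frozen = np.array([synthetic.TETRAD_PHI, synthetic.TETRAD_ALPHA,
                       synthetic.DEFAULT_C1_RADIUS])
    print("matches frozen constants:",
          bool(np.allclose(best.x, frozen, atol=1e-6)))


if __name__ == "__main__":
    main()
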