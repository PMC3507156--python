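"""Regenerate the embedded four-level Ramachandran region grid.

Writes ``src/triadcore/data/rama_grid.txt``: a 36x36 grid of 10-degree
phi-psi cells graded F (most favoured), A (additionally allowed),
G (generously allowed) or D (disallowed), following the conventional
four-level region map used for backbone validation (core alpha, beta
and left-handed-alpha regions, their allowed surroundings, and a
~20-degree generously-allowed margin dilated on the phi-psi torus).

Run from the repository root:  python scripts/make_rama_grid.py
"""

from __future__ import annotations

from pathlib import Path

N = 36  # 10-degree bins from -180 to 180


def centers() -> list[float]:
    return [-175.0 + 10.0 * i for i in range(N)]


def in_rect(phi: float, psi: float, rect: tuple[float, float, float, float]) -> bool:
    p0, p1, s0, s1 = rect
    return p0 <= phi <= p1 and s0 <= psi <= s1


# rectangles over cell centers: (phi_min, phi_max, psi_min, psi_max)
FAVOURED = [
    (-165, -55, 105, 175),    # beta core
    (-165, -95, -175, -175),  # beta core wrap across psi = 180
    (-155, -45, -65, -15),    # right-handed alpha core
    (45, 65, 25, 65),         # left-handed alpha core
]

ALLOWED = [
    (-175, -45, 65, 175),     # beta + polyproline II surroundings
    (-175, -45, -175, -165),  # beta wrap tail
    (-175, -35, -85, -5),     # alpha surroundings
    (-105, -45, -5, 75),      # alpha/beta bridge channel
    (35, 75, 5, 85),          # left-handed alpha surroundings
    (55, 85, 165, 175),       # epsilon region
    (55, 85, -175, -165),     # epsilon region wrap
]


def build() -> list[list[str]]:
    cs = centers()
    grid = [["D"] * N for _ in range(N)]
    for i, phi in enumerate(cs):
        for j, psi in enumerate(cs):
            if any(in_rect(phi, psi, r) for r in ALLOWED):
                grid[i][j] = "A"
    for i, phi in enumerate(cs):
        for j, psi in enumerate(cs):
            if any(in_rect(phi, psi, r) for r in FAVOURED):
                grid[i][j] = "F"
    # generous margin: within 2 cells (Chebyshev, toroidal) of F or A
    out = [row[:] for row in grid]
    for i in range(N):
        for j in range(N):
            if grid[i][j] != "D":
                continue
            near = False
            for di in range(-2, 3):
                for dj in range(-2, 3):
                    if grid[(i + di) % N][(j + dj) % N] in ("F", "A"):
                        near = True
            if near:
                out[i][j] = "G"
    return out


def main() -> None:
    grid = build()
    dest = Path(__file__).resolve().parents[1] / "src/triadcore/data/rama_grid.txt"
    lines = [
        "# Four-level Ramachandran region grid, version 1",
        "# 36 rows = phi bins ascending from -180 in 10-degree steps;",
        "# 36 columns = psi bins ascending from -180.",
        "# F most favoured / A additionally allowed / G generously allowed / D disallowed",
    ]
    lines += ["".join(row) for row in grid]
    dest.write_text("\n".join(lines) + "\n")
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
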