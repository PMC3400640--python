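"""Numba-compiled numerical kernels.

Everything here operates on plain float64/uint8 arrays so the hot path of the
sampler (one backbone build + one staged score per fragment-insertion move)
stays allocation-light. Angles enter in degrees; conversion to radians happens
only inside these kernels.

Ideal backbone geometry (Engh-Huber-like):
    bond lengths  N-CA 1.458, CA-C 1.525, C-N 1.329 (Angstrom)
    bond angles   N-CA-C 111.2, CA-C-N 116.2, C-N-CA 121.7 (degrees)
"""

import math

import numpy as np
from numba import njit

# bond lengths (A)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
# bond angles (rad)
A_N_CA_C = math.radians(111.2)
A_CA_C_N = math.radians(116.2)
A_C_N_CA = math.radians(121.7)

DEG = math.pi / 180.0

# energy constants
D_CLASH = 4.0          # CA-CA steric cutoff (A)
CONTACT_CUTOFF = 8.0   # hydrophobic contact distance (A)
RG_COEF = 2.2          # target Rg = RG_COEF * L**RG_EXP (A)
RG_EXP = 0.38

# ss codes: 0 = H, 1 = E, 2 = L (loop: always inside its basin)


@njit(cache=False)
def _place(ax, ay, az, bx, by, bz, cx, cy, cz, r, theta, chi):
    """Next atom D from three predecessors A-B-C, bond length r to C, bond
    angle theta at C (B-C-D) and dihedral chi (A-B-C-D)."""
    bcx = cx - bx
    bcy = cy - by
    bcz = cz - bz
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx /= nbc
    bcy /= nbc
    bcz /= nbc
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    # n = unit(ab x bc)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx /= nn
    ny /= nn
    nz /= nn
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    st = math.sin(theta)
    d0 = -r * math.cos(theta)
    d1 = r * st * math.cos(chi)
    d2 = r * st * math.sin(chi)
    dx = cx + bcx * d0 + mx * d1 + nx * d2
    dy = cy + bcy * d0 + my * d1 + ny * d2
    dz = cz + bcz * d0 + mz * d1 + nz * d2
    return dx, dy, dz


@njit(cache=False)
def nerf_backbone(phi, psi, omega):
    """Extend an ideal-geometry N/CA/C chain from backbone torsions (degrees).

    Returns coords with shape (L, 3, 3): axis 1 is (N, CA, C).
    phi[0], psi[L-1] and omega[L-1] are not used by the construction.
    """
    L = phi.shape[0]
    out = np.empty((L, 3, 3))
    if L == 0:
        return out
    # canonical first-residue frame: N at origin, CA on +x, C in the xy plane
    out[0, 0, 0] = 0.0
    out[0, 0, 1] = 0.0
    out[0, 0, 2] = 0.0
    out[0, 1, 0] = B_N_CA
    out[0, 1, 1] = 0.0
    out[0, 1, 2] = 0.0
    out[0, 2, 0] = B_N_CA - B_CA_C * math.cos(A_N_CA_C)
    out[0, 2, 1] = B_CA_C * math.sin(A_N_CA_C)
    out[0, 2, 2] = 0.0
    for i in range(1, L):
        # N(i): dihedral psi(i-1) about N(i-1)-CA(i-1)-C(i-1)
        nx, ny, nz = _place(
            out[i - 1, 0, 0], out[i - 1, 0, 1], out[i - 1, 0, 2],
            out[i - 1, 1, 0], out[i - 1, 1, 1], out[i - 1, 1, 2],
            out[i - 1, 2, 0], out[i - 1, 2, 1], out[i - 1, 2, 2],
            B_C_N, A_CA_C_N, psi[i - 1] * DEG,
        )
        out[i, 0, 0] = nx
        out[i, 0, 1] = ny
        out[i, 0, 2] = nz
        # CA(i): dihedral omega(i-1) about CA(i-1)-C(i-1)-N(i)
        cax, cay, caz = _place(
            out[i - 1, 1, 0], out[i - 1, 1, 1], out[i - 1, 1, 2],
            out[i - 1, 2, 0], out[i - 1, 2, 1], out[i - 1, 2, 2],
            nx, ny, nz,
            B_N_CA, A_C_N_CA, omega[i - 1] * DEG,
        )
        out[i, 1, 0] = cax
        out[i, 1, 1] = cay
        out[i, 1, 2] = caz
        # C(i): dihedral phi(i) about C(i-1)-N(i)-CA(i)
        cx, cy, cz = _place(
            out[i - 1, 2, 0], out[i - 1, 2, 1], out[i - 1, 2, 2],
            nx, ny, nz,
            cax, cay, caz,
            B_CA_C, A_N_CA_C, phi[i] * DEG,
        )
        out[i, 2, 0] = cx
        out[i, 2, 1] = cy
        out[i, 2, 2] = cz
    return out


@njit(cache=False)
def clash_score(ca):
    """Sum of (D_CLASH - d)^2 over CA pairs with |i-j| >= 3 and d < D_CLASH."""
    L = ca.shape[0]
    s = 0.0
    for i in range(L):
        for j in range(i + 3, L):
            dx = ca[i, 0] - ca[j, 0]
            dy = ca[i, 1] - ca[j, 1]
            dz = ca[i, 2] - ca[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < D_CLASH:
                t = D_CLASH - d
                s += t * t
    return s


@njit(cache=False)
def rg_score(ca):
    """(Rg - 2.2 * L**0.38)^2 over CA atoms."""
    L = ca.shape[0]
    mx = 0.0
    my = 0.0
    mz = 0.0
    for i in range(L):
        mx += ca[i, 0]
        my += ca[i, 1]
        mz += ca[i, 2]
    mx /= L
    my /= L
    mz /= L
    s = 0.0
    for i in range(L):
        dx = ca[i, 0] - mx
        dy = ca[i, 1] - my
        dz = ca[i, 2] - mz
        s += dx * dx + dy * dy + dz * dz
    rg = math.sqrt(s / L)
    t = rg - RG_COEF * L ** RG_EXP
    return t * t


@njit(cache=False)
def contact_score(ca, hydro):
    """-1 per hydrophobic-hydrophobic CA pair with |i-j| >= 4 and d < 8 A."""
    L = ca.shape[0]
    s = 0.0
    for i in range(L):
        if hydro[i] == 0:
            continue
        for j in range(i + 4, L):
            if hydro[j] == 0:
                continue
            dx = ca[i, 0] - ca[j, 0]
            dy = ca[i, 1] - ca[j, 1]
            dz = ca[i, 2] - ca[j, 2]
            if dx * dx + dy * dy + dz * dz < CONTACT_CUTOFF * CONTACT_CUTOFF:
                s -= 1.0
    return s


@njit(cache=False)
def ss_local_score(phi, psi, ss_code):
    """Count residues whose (phi, psi) lies outside the basin of the target
    secondary structure.  H: phi in [-100,-30], psi in [-80,-5];
    E: phi in [-180,-90], psi in [90,180]; L: always inside."""
    L = phi.shape[0]
    n = 0
    for i in range(L):
        c = ss_code[i]
        if c == 0:
            if phi[i] < -100.0 or phi[i] > -30.0 or psi[i] < -80.0 or psi[i] > -5.0:
                n += 1
        elif c == 1:
            if phi[i] < -180.0 or phi[i] > -90.0 or psi[i] < 90.0 or psi[i] > 180.0:
                n += 1
    return float(n)


@njit(cache=False)
def staged_score(phi, psi, omega, hydro, ss_code, weights):
    """Build the backbone and return the weighted sum of the four terms.

    weights: float64[4] in term order (clash, rg, contact, ss_local); a zero
    weight skips the term entirely.
    """
    coords = nerf_backbone(phi, psi, omega)
    ca = np.ascontiguousarray(coords[:, 1, :])
    e = 0.0
    if weights[0] != 0.0:
        e += weights[0] * clash_score(ca)
    if weights[1] != 0.0:
        e += weights[1] * rg_score(ca)
    if weights[2] != 0.0:
        e += weights[2] * contact_score(ca, hydro)
    if weights[3] != 0.0:
        e += weights[3] * ss_local_score(phi, psi, ss_code)
    return e


def warmup():
    """Trigger JIT compilation of every kernel on a tiny problem."""
    phi = np.full(5, -57.0)
    psi = np.full(5, -47.0)
    omega = np.full(5, 180.0)
    hydro = np.ones(5, dtype=np.uint8)
    ss = np.zeros(5, dtype=np.uint8)
    staged_score(phi, psi, omega, hydro, ss, np.ones(4))
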