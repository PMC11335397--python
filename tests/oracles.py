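"""Independent brute-force oracles for accessibility and overlap.

Deliberately written as explicit per-water-mass loops over the three niche
criteria, sharing no code with the vectorised implementation they check.
"""


def brute_force_accessible(patch, niche, wm):
    total = 0.0
    ny, nx, nk = wm.shape
    for i in range(ny):
        for j in range(nx):
            for k in range(nk):
                if not niche.mask.cells[i, j]:
                    continue
                if (k + 1) not in niche.strata:
                    continue
                if patch.d_patch_gm3[i, j, k] < niche.threshold_gm3:
                    continue
                total += patch.p[i, j, k] * patch.biomass_g[i, j, k]
    return total


def brute_force_shared(patch, niche_a, niche_b, wm):
    total = 0.0
    ny, nx, nk = wm.shape
    for i in range(ny):
        for j in range(nx):
            for k in range(nk):
                def ok(n):
                    return (
                        n.mask.cells[i, j]
                        and (k + 1) in n.strata
                        and patch.d_patch_gm3[i, j, k] >= n.threshold_gm3
                    )
                if ok(niche_a) and ok(niche_b):
                    total += patch.p[i, j, k] * patch.biomass_g[i, j, k]
    return total
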