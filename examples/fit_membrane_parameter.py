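"""Recover the environment-modulation parameter K from a profile generated
at a known K.

An "observed" profile is manufactured as M(T, K_true) plus a little noise;
the grid fit of D_KL(O | M(T, K)) should return a K close to K_true. This
is the calibration behind interpreting fitted K values on real structures.
"""

from fodm import SyntheticSpec, chain_status, fit_k, make_gaussian_micelle, make_profile_with_k

t = chain_status(make_gaussian_micelle(SyntheticSpec(n_residues=200, seed=0))).t

for k_true in (0.0, 0.5, 1.0, 2.0):
    o_clean = make_profile_with_k(t, k_true, noise_sd=0.0)
    o_noisy = make_profile_with_k(t, k_true, noise_sd=0.1 / len(t), seed=11)
    k_clean, _ = fit_k(o_clean, t)
    k_noisy, curve = fit_k(o_noisy, t)
    print(f"K_true = {k_true:3.1f}   recovered: {k_clean:3.1f} (noise-free), "
          f"{k_noisy:3.1f} (noisy)")

print()
print("Noise-free recovery is exact (the generator's K is a grid point);")
print("with noise ~0.1/N on the probability scale it stays within ~0.2.")
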