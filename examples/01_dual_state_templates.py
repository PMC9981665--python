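"""Dual-state residue templates and the polarizable-parameter transforms.

Loads the packaged 1-methylimidazolium acetate configuration: each
exchangeable residue carries two complete parameter sets (protonated and
deprotonated) over one shared atom list, with the transferable hydrogen
kept as a zero-charge dummy in the deprotonated state.
"""

import pexkit as pk

templates, reactions = pk.imidazolium_acetate_templates()

print("Residue templates (net charge per protonation state):")
for t in templates:
    print(
        f"  {t.name_protonated:>5s} ({t.net_charge(t.name_protonated):+d} e)"
        f"  <->  {t.name_deprotonated:<5s} ({t.net_charge(t.name_deprotonated):+d} e)"
        f"   donor={','.join(t.donor_atoms)}"
        f" acceptor={','.join(t.acceptor_atoms)}"
        f" violations={pk.validate_mapping(t)}"
    )

imid = templates[0]
h7 = next(a for a in imid.atoms_deprotonated if a.atom_name == "H7")
print(
    f"\nTransferable H7 in the deprotonated state: type={h7.atom_type}, "
    f"q={h7.charge} e (a dummy atom: present in the topology, inert)."
)

print("\nTransfer reactions (distance cutoff, reference probability, feedback c):")
for r in reactions:
    kind = "swap" if r.is_swap else "charge-changing"
    print(f"  {r.name:<24s} r_max={r.r_max} A  p_ref={r.p_ref:.3f}  c={r.c:.0f}  [{kind}]")

# Drude-oscillator bookkeeping: charge from polarizability at fixed spring k
alpha, k = 1.0, 1000.0
q_d = pk.drude_charge_from_polarizability(alpha, k)
print(
    f"\nDrude charge for alpha={alpha} A^3 at k={k:.0f} kcal/mol/A^2: "
    f"q_d = {q_d:.4f} e (k recovered: {pk.drude_force_constant(alpha, q_d):.6f})"
)

# LJ well depths shrink with polarizability to avoid double-counted dispersion
eps0, amax, s = 0.10, 2.0, 0.25
for a in (0.0, 1.0, 2.0):
    print(
        f"eps(alpha={a:.1f}) = {pk.scale_lj_epsilon(eps0, a, amax, s):.4f} kcal/mol"
        + ("   (unscaled limit)" if a == 0 else "   (= s*eps limit)" if a == amax else "")
    )

print(
    f"\nSelf-polarization energy of one Drude pair displaced 0.1 A: "
    f"{pk.self_polarization_energy([[0.1, 0.0, 0.0]], k):.1f} kcal/mol"
)
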