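# freemetal

Free metal-ion speciation in chelator buffers.

Experimentalists buffering Ca²⁺, Mg²⁺ or Zn²⁺ with EGTA, EDTA or ATP need
to know the *free* metal-ion concentration their recipe produces — or,
inversely, how much total metal to add to hit a target free concentration
(e.g., a pCa between 5 and 6 for muscle-activation work). Direct
measurement with ion-selective electrodes is often impractical, so the
concentration is computed from stability constants. `freemetal` does that
computation as a tested library and CLI.

## The model

Stability constants are quoted as log₁₀ association constants at a
reference temperature and ionic strength. For each metal M and chelator L
the package builds the **apparent (conditional) constant** at the working
conditions:

1. **van't Hoff temperature correction** per constant with its reaction
   enthalpy ΔH°:
   log K(T) = log K(T_ref) − (ΔH°/(ln10·R))·(1/T − 1/T_ref);
2. **extended Debye–Hückel activity correction** in the ionic equivalence
   Ie = ½·ΣCᵢ·|zᵢ| (the charge-weighted sum this calculator lineage uses in
   place of the standard ionic strength):
   log K(I) = log K(I_ref) − Δz²·(f(I) − f(I_ref)), with
   f(I,T) = A(T)·(√I/(1+√I) − 0.25·I) and Δz² = Σz²(reactants) − z²(product);
3. **proton competition** at the working pH through the fraction of
   unbound ligand that is fully deprotonated,
   α = 1 / (1 + Σᵢ (Π_{j≤i} K_Hj)·[H⁺]ⁱ), giving
   K_app = α · Σₙ β_MHₙL·[H⁺]ⁿ.

K_app relates free metal to the total unbound ligand pool, so a mixture of
metals and chelators reduces to the coupled mass balances

    M_T,m = M_free,m · (1 + Σⱼ K_app(m,j)·L_free,j)
    L_T,j = L_free,j · (1 + Σₘ K_app(m,j)·M_free,m)

solved by damped alternating fixed-point iteration (with a bisection
fallback), in native floats or in arbitrary-precision decimal arithmetic
(default 50 significant digits) via the standard-library `decimal` module.

Four built-in constant sources (NIST, Chelator, SPECS, Calcium lineages)
ship as JSON data files; user-defined sets use the same schema-validated
JSON interchange format. Chelator purity, input units from M to nM, pX
output, session accumulation and Excel/CSV export are built in.

## Worked example

0.5 mM total CaCl₂ in 1 mM EGTA (97 % pure) + 2 mM ATP + 6 mM MgCl₂ at
pH 7.0, 20 °C, Ie 100 mM:

```sh
freemetal calc --source NIST --temp 20 --ph 7.0 --ie 100 \
    --chelator EGTA=1mM@97% --chelator ATP=2mM \
    --metal Mg=6mM:total --metal Ca=0.5mM:total
```

prints (abridged):

```json
{
  "metals": {
    "Mg": {"free_m": 0.003960226479078647, "px": 2.402279976750856},
    "Ca": {"free_m": 2.709225785435974e-07, "px": 6.5671547995874295}
  },
  "ligands": {
    "EGTA": {"total_effective_m": 0.00097, "free_unbound_m": 0.00039175916029445603}
  },
  "convergence": {"iterations": 114, "residual": 9.74999541298047e-13}
}
```

Reading: with EGTA about half loaded, free Ca is 271 nM (pCa 6.57); ATP
holds most of the Mg (free Mg ≈ 3.96 mM of 6 mM); the purity field reduced
the effective EGTA to 0.97 mM. Mass balance closes to ~10⁻¹² relative.

The same computation in Python:

```python
import freemetal as fm

cond = fm.BufferConditions(temperature=20.0, ph=7.0, ionic_equivalence=100.0)
table = fm.build_table(fm.load_builtin("NIST"), ["Ca", "Mg"], ["EGTA", "ATP"], cond)
mix = fm.MixtureSpec(
    (fm.ChelatorEntry("EGTA", 1.0, "mM", purity=97.0), fm.ChelatorEntry("ATP", 2.0, "mM")),
    (fm.MetalEntry("Ca", 0.5, "mM"), fm.MetalEntry("Mg", 6.0, "mM")),
    cond,
)
result = fm.solve_free_from_total(mix, table)
print(result.metals["Ca"].px)   # 6.5671547995874295
```

Other subcommands: `freemetal ie Na:150 Cl:-1:150` (ionic-equivalence
helper, prints `150 mM`), `freemetal constants list|dump|validate`
(constant-set management), `freemetal adjust` (apparent-constant table as
CSV — at the conditions above, log K_app(Ca, EGTA) = 6.672813 with
α = 6.50×10⁻⁵).

## Layout

- `src/freemetal/constants_store.py` — constant sets, JSON interchange, validation
- `src/freemetal/apparent_constants.py` — the three corrections, tables
- `src/freemetal/equilibrium_solver.py` — mass-balance solver, precision contexts
- `src/freemetal/reporting_io.py` — units, Ie helper, sessions, XLSX/CSV export
- `src/freemetal/cli.py` — `freemetal` command
- `src/freemetal/fixtures.py` — synthetic sets, random mixtures, brute-force oracle
- `docs/methods.md` — model details, conventions, numerical choices, limitations
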