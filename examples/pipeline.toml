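# Full-pipeline configuration: `defectometer run --config examples/pipeline.toml`
output_dir = "scratch/pipeline_toml_demo"

[soap]
nmax = 8
lmax = 8
rcut = 0.8     # nm; 1.6 / 3.0 probe wider environments
sigma = 0.1    # nm

[pooling]
n_per_system = 1000
seed = 0

[reduction]
n_components = 3

[clustering]
K = 3          # macrostate count (2 for droplets, 3 for fibers/bilayers)
n_boot = 73
seed = 0

[dynamics]
lag = 1        # frames

[[systems]]
id = "fiber_defected"
[systems.synthetic]
kind = "fiber"
n_monomers = 150
n_frames = 20
seed = 1
state_fractions = [0.85, 0.10, 0.05]

[[systems]]
id = "shell"
[systems.synthetic]
kind = "shell"
n_monomers = 150
n_frames = 20
seed = 2

# On-disk trajectories work the same way:
# [[systems]]
# id = "my_system"
# trajectory = "my_system.xyz"   # extended XYZ, Lattice= box on comment line
# format = "extended-xyz"
# selection = [[0, 1, 2], [3, 4, 5]]   # optional bead groups -> COG centers
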