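# Full-pipeline configuration for `pollenscape all --config examples/pipeline.toml`.
# Input paths assume you first ran:
#   pollenscape simulate --seed 42 --outdir scratch/demo
landcover = "scratch/demo/landcover.tif"
sites = "scratch/demo/sites.geojson"
genotypes = "scratch/demo/genotypes.csv"
captures = "scratch/demo/captures.csv"
responses = "scratch/demo/responses.csv"
outdir = "scratch/demo/analysis"
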