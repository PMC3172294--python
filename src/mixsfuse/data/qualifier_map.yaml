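# Default MIxS short_name -> INSDC source-modifier name map.
# The domain of this map defines which checklist fields are header-destined;
# everything else goes to the structured comment. Override with a file of the
# same shape via Registry/CLI options.
lat_lon: lat_lon
collection_date: collection_date
geo_loc_name: country
isolation_source: isolation_source
host: host
strain: strain
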