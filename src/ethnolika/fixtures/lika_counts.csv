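taxon_id,fc,FO,MD,AL,AF,CT,CE,OT
abies_alba,11,,,,,,,
acer_obtusatum,2,,,,,,,
achillea_millefolium,37,,37,1,3,,,
aesculus_hippocastaneum,2,,,,,,,
agrimonia_eupatoria,2,,,,,,,
allium_ampeloprasum,3,,,,,,,
allium_cepa,2,,,,,,,
amaranthus_retroflexus,2,,,,,,,
amelanchier_ovalis,2,,,,,,,
arctium_lappa,4,,,,,,,
artemisia_absinthium,17,,,8,,,,
arum_maculatum,16,,,,16,,,
avena_sativa,2,,,,,,,
bellis_perennis,3,,,,,,,
beta_vulgaris_crassa,3,,,,,,,
betula_pendula,2,,,,,,,
brassica_oleracea,2,,,,,,,
calendula_arvensis,2,,,,,,,
cannabis_sativa,7,,,,,,,
carum_carvi,22,,21,,,,,
chelidonium_majus,3,,,,,,,
chenopodium_album,13,,,,,,,
cichorium_intybus,4,,,,,,,
cirsium_arvense,15,,,,15,,,
convolvulus_arvensis,14,,,,,,,
cornus_mas,33,30,1,17,,1,14,
corylus_avellana,25,19,,,5,11,,1
crataegus_monogyna,31,24,11,1,,,,
crocus_sp,4,,,,,,,
cydonia_oblonga,20,,,,,,,
elymus_repens,2,,,,,,,
fagus_sylvatica,14,,,,,3,,
fragaria_vesca,23,,,,,,,
fraxinus_excelsior,7,,,,,,,
galanthus_nivalis,2,,,,,,,
gentiana_lutea,2,,,,,,,
hedera_helix,13,,,,,,13,
helleborus_dumetorum,9,,,,,,,
hordeum_vulgare,2,,,,,,,
hypericum_perforatum,12,,,,,,,
juglans_regia,30,25,,19,,2,,
juniperus_communis,7,,,,,,,
linum_usitatissimum,2,,,,,,,
lotus_corniculatus,2,,,,,,,
malus_domestica,19,,,,,,,
matricaria_chamomilla,14,,,,,,,
melissa_officinalis,2,,,,,,,
mentha_spp,9,,,,,,,
mespilus_germanica,2,,,,,,,
morus_alba,10,,,,,,,
nicotiana_tabacum,2,,,,,,,
panicum_miliaceum,2,,,,,,,
phaseolus_vulgaris,4,,,,,,,
picea_abies,7,,,,,,,
plantago_lanceolata,11,,,,,,,
plantago_major,8,,,,,,,
primula_vulgaris,17,,,,,,8,
prunus_avium,7,,,,,,,
prunus_domestica,32,31,,18,,,,
prunus_domestica_insititia,4,,,,,,,
prunus_mahaleb,2,,,,,,,
prunus_spinosa,31,28,,,,,,
pulmonaria_officinalis,2,,,,,,,
pyrus_communis,14,,,8,,,,
pyrus_communis_tepka,6,,,,,,,
pyrus_pyraster,8,,,,,,,
quercus_petraea,2,,,,,,,
quercus_robur,16,,,,16,,,
rhamnus_alpina_fallax,2,,,,,,,
ribes_uva_crispa,5,,,,,,,
robinia_pseudoacacia,2,,,,,,,
rosa_canina,36,30,8,1,,,,
rubus_caesius,24,,,,,,,
rubus_idaeus,14,,,,,,,
rumex_acetosa,10,,,,,,,
rumex_pulcher,23,,14,,18,,,
salix_purpurea,4,,,,,3,,
salvia_officinalis,7,,,,,,,
sambucus_ebulus,7,,,,,,,
sambucus_nigra,32,24,11,,,,,
satureja_montana,2,,,,,,,
satureja_subspicata,5,,,,,,,
scorzonera_villosa,3,,,,,,,
secale_cereale,4,,,,,4,,
sempervivum_tectorum,11,,,,,,,
silene_vulgaris,4,,,,,,,
silybum_marianum,3,,,,,,,
sorbus_aria,9,,,,,,,
sorbus_domestica,6,,,,,,,
sorbus_torminalis,12,,,,,,,
symphytum_officinale,5,,,,,,,
tanacetum_balsamita,4,,,,,,,
taraxacum_ruderalia,32,3,13,,21,,,1
thymus_serpyllum,13,,,,,,,
tilia_platyphyllos,25,,14,,,,,
trifolium_pratense,9,,,,,,,
trifolium_repens,3,,,,,,,
triticum_aestivum,2,,,,,,,
triticum_spelta,2,,,,,,,
tussilago_farfara,3,,,,,,,
ulmus_glabra,2,,,,,,,
urtica_dioica,31,23,4,,14,,,
valerianella_locusta,2,,,,,,,
veratrum_sp,4,,,,,,,
verbascum_pulverulentum,3,,,,,,,
verbena_officinalis,2,,,,,,,
vinca_minor,11,,,,,,11,
viola_odorata,27,,,,,,27,
viscum_album,6,,,,,,,
vitis_vinifera,2,,,,,,,
zea_mays,3,,,,,,,
agaricus_campestris,20,,,,,,,
boletus_sect_boletus,6,,,,,,,
cantharellus_cibarius,4,,,,,,,
morchella_sp,1,,,,,,,
taphrina_pruni,3,,,,,,,
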