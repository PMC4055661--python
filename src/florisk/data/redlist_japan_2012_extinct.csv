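scientific_name,category
Lycopodium cunninghamioides,EX
Botrychium boreale,EX
Ophioglossum parvifolium,EX
Hypolepis tenuifolia,EX
Asplenium austrochinense,EX
Arachniodes yasu-inouei var. angustipinnula,EX
Tectaria dissecta,EX
Pyrrosia angustissima,EX
Elatostema lineolatum var. majus,EX
Ranunculus gmelinii,EX
Rubus hatsushimae,EX
Flemingia strobilifera,EX
Lespedeza hisauchii,EX
Euphrasia insignis subsp. insignis var. omiensis,EX
Euphrasia insignis subsp. insignis var. pubigera,EX
Euphrasia multifolia var. kirisimana,EX
Cirsium toyoshimae,EX
Aletris makiyataroi,EX
Burmannia coelestris,EX
Thismia tuberculata,EX
Eriocaulon cauliferum,EX
Eriocaulon seticuspe,EX
Carex disperma,EX
Cyperus diaphanus,EX
Cyperus procerus,EX
Fimbristylis leptoclada var. takamineana,EX
Fimbristylis pauciflora,EX
Acanthophippium striatum,EX
Neottia kiusiana,EX
Odontochilus poilanei,EX
Renanthera labrosa,EX
Zeuxine boninensis,EX
Thelypteris aurita,EW
Dryopteris shibipedis,EW
Magnolia pseudokobus,EW
Kalanchoe spathulata,EW
Malus hupehensis,EW
Astragalus sikokianus,EW
Viola stoloniflora,EW
Lycoris sanguinea var. koreana,EW
Eriocaulon heleocharioides,EW
Liparis uchiyamae,EW
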